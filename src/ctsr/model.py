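"""The super-resolution network: low-frequency feature extraction, a stack
of attention transformer blocks (ATBs) built from swin transformer layers
(STLs), and a pixel-shuffle reconstruction head.

Given a low-resolution image ``I_LQ``, the network computes

    F_0    = H_LF(I_LQ)               shallow conv features (3x3, 1x1, 3x3)
    F_DF   = H_DF(F_0)                num_atbs ATBs applied sequentially
    I_RHQ  = H_REC(F_0 + F_DF)        conv -> pixel shuffle -> conv

Each ATB applies ``L`` STLs followed by a 3x3 convolution and a block-level
residual: ``F_out = conv(STL_L(...STL_1(F_in))) + F_in``.  Each STL is a
pre-norm transformer block over M x M windows:
``X <- X + MSA(LN(X))`` then ``X <- X + MLP(LN(X))``, with the window
partition cyclically shifted by ``M // 2`` on odd-indexed STLs so windows
communicate.  The F_0 skip connection carries low-frequency content
directly to the reconstruction head, leaving the transformer stack to model
high-frequency detail (edges, texture).

Public methods accept and return channels-first arrays (``(C, h, w)`` or
``(B, C, h, w)``); internally everything runs channels-last (see ``nn``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .window_attention import WindowMSA, build_shift_mask

RECON_WIDTH = 64   # channel width of the reconstruction head after each shuffle


@dataclass
class ModelConfig:
    """Architectural hyperparameters.

    Defaults follow the published configuration where one is stated
    (6 ATBs of 6 STLs, window size 8) and otherwise use a width that keeps
    the model CPU-trainable (embed_dim 60, 6 heads, MLP ratio 2).
    """

    scale: int = 2
    in_channels: int = 1
    embed_dim: int = 60
    num_atbs: int = 6
    stls_per_atb: int = 6
    window_size: int = 8
    num_heads: int = 6
    mlp_ratio: float = 2.0
    use_rel_bias: bool = True
    init_seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.scale not in (2, 4):
            raise ValueError("scale must be 2 or 4")
        if self.in_channels not in (1, 3):
            raise ValueError("in_channels must be 1 or 3")
        if self.embed_dim % self.num_heads != 0:
            raise ValueError("embed_dim must be divisible by num_heads")
        if self.num_atbs < 0 or self.stls_per_atb < 1 or self.window_size < 1:
            raise ValueError("block counts must be positive (num_atbs may be 0)")
        if self.mlp_ratio <= 0:
            raise ValueError("mlp_ratio must be positive")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


class LowFreqExtractor(nn.Module):
    """Shallow conv stack H_LF: 3x3 -> 1x1 -> 3x3, preserving spatial size."""

    def __init__(self, in_ch, embed_dim, rng, dtype):
        self.conv1 = nn.Conv2d(in_ch, embed_dim, 3, rng, dtype)
        self.conv2 = nn.Conv2d(embed_dim, embed_dim, 1, rng, dtype)
        self.conv3 = nn.Conv2d(embed_dim, embed_dim, 3, rng, dtype)

    def forward(self, x):
        return self.conv3.forward(self.conv2.forward(self.conv1.forward(x)))

    def backward(self, dy):
        return self.conv1.backward(self.conv2.backward(self.conv3.backward(dy)))


class SwinLayer(nn.Module):
    """One STL: windowed MSA and a position-wise MLP, both pre-norm residual.

    Channels-last: ``(B, h, w, C)`` in and out.
    """

    def __init__(self, cfg: ModelConfig, shift: int, rng):
        dtype = cfg.np_dtype
        self.shift = shift
        self.window_size = cfg.window_size
        self.ln1 = nn.LayerNorm(cfg.embed_dim, dtype=dtype)
        self.msa = WindowMSA(cfg.embed_dim, cfg.num_heads, cfg.window_size, rng,
                             cfg.use_rel_bias, dtype)
        self.ln2 = nn.LayerNorm(cfg.embed_dim, dtype=dtype)
        hidden = int(round(cfg.mlp_ratio * cfg.embed_dim))
        self.fc1 = nn.Linear(cfg.embed_dim, hidden, rng, dtype=dtype)
        self.act = nn.GELU()
        self.fc2 = nn.Linear(hidden, cfg.embed_dim, rng, dtype=dtype)
        self._mask_cache = {}
        self._geom = None

    def _mask_for(self, h, w):
        if self.shift == 0:
            return None
        key = (h, w)
        if key not in self._mask_cache:
            self._mask_cache[key] = build_shift_mask(
                h, w, self.window_size, self.shift).bias
        return self._mask_cache[key]

    def _to_windows(self, t):
        """(B, h, w, C) -> (B * nW, M^2, C) with reflect pad + cyclic shift."""
        B, h, w, C = t.shape
        m = self.window_size
        ph, pw = (-h) % m, (-w) % m
        if ph or pw:
            t = np.pad(t, ((0, 0), (0, ph), (0, pw), (0, 0)), mode="reflect")
        if self.shift:
            t = np.roll(t, (-self.shift, -self.shift), axis=(1, 2))
        hp, wp = h + ph, w + pw
        x = t.reshape(B, hp // m, m, wp // m, m, C).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(x).reshape(-1, m * m, C), (hp, wp)

    def _from_windows(self, wins, B, h, w, hp, wp):
        m = self.window_size
        C = wins.shape[-1]
        x = wins.reshape(B, hp // m, wp // m, m, m, C).transpose(0, 1, 3, 2, 4, 5)
        x = np.ascontiguousarray(x).reshape(B, hp, wp, C)
        if self.shift:
            x = np.roll(x, (self.shift, self.shift), axis=(1, 2))
        return x[:, :h, :w, :]

    def forward(self, x):
        B, h, w, C = x.shape
        m = self.window_size
        ph, pw = (-h) % m, (-w) % m
        if (ph and ph >= h) or (pw and pw >= w):
            raise ValueError(
                f"spatial size {h}x{w} too small to reflect-pad to window size {m}")
        n1 = self.ln1.forward(x)
        wins, (hp, wp) = self._to_windows(n1)
        attn = self.msa.forward(wins, self._mask_for(h, w))
        x = x + self._from_windows(attn, B, h, w, hp, wp)
        n2 = self.ln2.forward(x)
        x = x + self.fc2.forward(self.act.forward(self.fc1.forward(n2)))
        self._geom = (B, h, w, hp, wp)
        return x

    def backward(self, dy):
        B, h, w, hp, wp = self._geom
        m = self.window_size
        # MLP branch
        dn2 = self.fc1.backward(self.act.backward(self.fc2.backward(dy)))
        dy = dy + self.ln2.backward(dn2)
        # attention branch: adjoint of crop -> un-roll -> partition
        C = dy.shape[-1]
        dmerged = np.zeros((B, hp, wp, C), dtype=dy.dtype)
        dmerged[:, :h, :w, :] = dy
        if self.shift:
            dmerged = np.roll(dmerged, (-self.shift, -self.shift), axis=(1, 2))
        dwins = dmerged.reshape(B, hp // m, m, wp // m, m, C).transpose(0, 1, 3, 2, 4, 5)
        dwins = np.ascontiguousarray(dwins).reshape(-1, m * m, C)
        dattn_in = self.msa.backward(dwins)
        # adjoint of partition -> shift -> reflect pad
        dx = dattn_in.reshape(B, hp // m, wp // m, m, m, C).transpose(0, 1, 3, 2, 4, 5)
        dx = np.ascontiguousarray(dx).reshape(B, hp, wp, C)
        if self.shift:
            dx = np.roll(dx, (self.shift, self.shift), axis=(1, 2))
        dn1 = _fold_reflect_pad(dx, h, w)
        return dy + self.ln1.backward(dn1)


def _fold_reflect_pad(dx_padded, h, w):
    """Accumulate gradients from reflect-padded rows/cols onto their sources.

    Channels-last: dx_padded is (B, hp, wp, C); padded row ``h + i`` mirrors
    source row ``h - 2 - i``.
    """
    B, hp, wp, C = dx_padded.shape
    dx = dx_padded
    ph, pw = hp - h, wp - w
    if ph:
        for i in range(ph):
            dx[:, h - 2 - i, :, :] += dx[:, h + i, :, :]
        dx = dx[:, :h, :, :]
    if pw:
        for j in range(pw):
            dx[:, :, w - 2 - j, :] += dx[:, :, w + j, :]
        dx = dx[:, :, :w, :]
    return np.ascontiguousarray(dx)


class ATB(nn.Module):
    """Attention transformer block: L STLs, a 3x3 conv, and a residual add."""

    def __init__(self, cfg: ModelConfig, rng):
        # even-indexed STLs unshifted, odd-indexed shifted by M // 2
        self.stls = [SwinLayer(cfg, 0 if j % 2 == 0 else cfg.window_size // 2, rng)
                     for j in range(cfg.stls_per_atb)]
        self.conv = nn.Conv2d(cfg.embed_dim, cfg.embed_dim, 3, rng, cfg.np_dtype)

    def forward(self, x):
        y = x
        for stl in self.stls:
            y = stl.forward(y)
        return self.conv.forward(y) + x

    def backward(self, dy):
        d = self.conv.backward(dy)
        for stl in reversed(self.stls):
            d = stl.backward(d)
        return d + dy


class Reconstructor(nn.Module):
    """H_REC: conv to 64*4 channels, x2 pixel shuffle (repeated for x4),
    and a final 3x3 conv back to image channels."""

    def __init__(self, cfg: ModelConfig, rng):
        dtype = cfg.np_dtype
        self.stages = []
        in_ch = cfg.embed_dim
        for _ in range(cfg.scale // 2):
            self.stages.append(nn.Conv2d(in_ch, RECON_WIDTH * 4, 3, rng, dtype))
            self.stages.append(nn.PixelShuffle(2))
            in_ch = RECON_WIDTH
        self.final = nn.Conv2d(RECON_WIDTH, cfg.in_channels, 3, rng, dtype)

    def forward(self, x):
        for layer in self.stages:
            x = layer.forward(x)
        return self.final.forward(x)

    def backward(self, dy):
        d = self.final.backward(dy)
        for layer in reversed(self.stages):
            d = layer.backward(d)
        return d


def _to_cl(x):
    """Channels-first (B, C, h, w) -> channels-last (B, h, w, C)."""
    return np.ascontiguousarray(np.moveaxis(x, 1, 3))


def _to_cf(x):
    return np.ascontiguousarray(np.moveaxis(x, 3, 1))


class STAN(nn.Module):
    """The full super-resolution network (channels-first public API)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        dtype = config.np_dtype
        self.lfe = LowFreqExtractor(config.in_channels, config.embed_dim, rng, dtype)
        self.atbs = [ATB(config, rng) for _ in range(config.num_atbs)]
        self.recon = Reconstructor(config, rng)

    @staticmethod
    def _batched(x, channels, what):
        x = np.asarray(x)
        squeeze = x.ndim == 3
        if squeeze:
            x = x[None]
        if x.ndim != 4 or x.shape[1] != channels:
            raise ValueError(f"expected {channels}-channel {what}, got shape {x.shape}")
        return x, squeeze

    # --- forward pieces -------------------------------------------------
    def lfe_forward(self, img: np.ndarray) -> np.ndarray:
        """Shallow feature extraction F_0 = H_LF(I_LQ)."""
        x, squeeze = self._batched(np.asarray(img, dtype=self.config.np_dtype),
                                   self.config.in_channels, "image")
        f0 = _to_cf(self.lfe.forward(_to_cl(x)))
        return f0[0] if squeeze else f0

    def deep_features(self, f0: np.ndarray) -> np.ndarray:
        """F_DF: sequential application of all ATBs (identity when none)."""
        x, squeeze = self._batched(f0, self.config.embed_dim, "feature map")
        y = _to_cl(x)
        for atb in self.atbs:
            y = atb.forward(y)
        y = _to_cf(y)
        return y[0] if squeeze else y

    def reconstruct(self, f0: np.ndarray, fdf: np.ndarray) -> np.ndarray:
        """I_RHQ = H_REC(F_0 + F_DF)."""
        if np.shape(f0) != np.shape(fdf):
            raise ValueError("F_0 and F_DF must have identical shapes")
        s, squeeze = self._batched(np.asarray(f0) + np.asarray(fdf),
                                   self.config.embed_dim, "feature map")
        y = _to_cf(self.recon.forward(_to_cl(s)))
        return y[0] if squeeze else y

    def forward(self, img: np.ndarray) -> np.ndarray:
        """Super-resolve: output spatial size = input size x scale."""
        x, squeeze = self._batched(np.asarray(img, dtype=self.config.np_dtype),
                                   self.config.in_channels, "image")
        f0 = self.lfe.forward(_to_cl(x))
        fdf = f0
        for atb in self.atbs:
            fdf = atb.forward(fdf)
        y = self.recon.forward(f0 + fdf)
        if not np.all(np.isfinite(y)):
            raise RuntimeError("non-finite activations in forward pass")
        y = _to_cf(y)
        return y[0] if squeeze else y

    __call__ = forward

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Backpropagate a loss gradient on the output image; accumulates
        parameter gradients and returns the input-image gradient."""
        squeeze = dy.ndim == 3
        ds = self.recon.backward(_to_cl(dy[None] if squeeze else dy))
        dfdf = ds
        for atb in reversed(self.atbs):
            dfdf = atb.backward(dfdf)
        # F_0 feeds both the ATB chain input and the skip sum
        dx = _to_cf(self.lfe.backward(ds + dfdf))
        return dx[0] if squeeze else dx


# --- checkpoints --------------------------------------------------------

def save_checkpoint(model: STAN, path, extra: dict | None = None):
    """Single-file weights archive with the JSON model config embedded."""
    arrays = {f"param/{k}": p.data for k, p in model.named_parameters()}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    if extra:
        for k, v in extra.items():
            arrays[f"extra/{k}"] = np.asarray(v)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[STAN, dict]:
    """Rebuild a model from a checkpoint; rejects config/weight mismatches."""
    with np.load(path) as data:
        if "config_json" not in data.files:
            raise ValueError("not a model checkpoint (missing embedded config)")
        cfg_raw = bytes(data["config_json"]).decode()
        config = ModelConfig(**json.loads(cfg_raw))
        model = STAN(config)
        extra = {}
        seen = set()
        for key in data.files:
            if key.startswith("param/"):
                seen.add(key[len("param/"):])
            elif key.startswith("extra/"):
                extra[key[len("extra/"):]] = data[key]
        names = dict(model.named_parameters())
        if set(names) != seen:
            raise ValueError("checkpoint parameter set does not match config")
        for name, p in names.items():
            stored = data[f"param/{name}"]
            if stored.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {name}")
            p.data[...] = stored
    return model, extra
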
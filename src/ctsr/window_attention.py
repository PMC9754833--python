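"""Window partitioning, cyclic shifting, masking and windowed multi-head
self-attention.

A feature map of size ``H x W x C`` is split into non-overlapping ``M x M``
local windows, giving ``HW / M^2`` windows of ``M^2`` tokens each, and
self-attention is computed independently inside every window.  Alternate
layers cyclically shift the map by ``M // 2`` before partitioning so that
information mixes across window boundaries; at the wrap-around seams the
shifted partition glues together tokens that were not spatial neighbours,
which is corrected by an additive attention mask that sends cross-region
logits to a large negative value.

Feature maps are channels-first ``(C, h, w)``; window tensors are
``(n_windows, M^2, C)`` with tokens in raster order inside each tile.
Non-divisible spatial sizes are reflect-padded up to multiples of ``M``
before partitioning and cropped after merging, so partition/merge is an
exact round-trip for every shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

#: Additive logit for masked (cross-region) attention pairs.  Finite rather
#: than -inf so the softmax never produces NaNs; after softmax the masked
#: pairs receive weight < 1e-12.
MASK_VALUE = -1e9


@dataclass
class WindowSet:
    """Feature map re-partitioned into flat attention windows."""

    windows: np.ndarray          # (n_windows, M^2, C)
    origin_shape: tuple          # (h, w) before padding
    window_size: int
    shift: int

    def __post_init__(self):
        if not 0 <= self.shift < self.window_size:
            raise ValueError("shift must lie in [0, window_size)")
        h, w = self.origin_shape
        hp, wp = _padded_size(h, self.window_size), _padded_size(w, self.window_size)
        expected = (hp // self.window_size) * (wp // self.window_size)
        if self.windows.ndim != 3 or self.windows.shape[0] != expected:
            raise ValueError(
                f"window count {self.windows.shape[0]} inconsistent with "
                f"origin shape {self.origin_shape} and M={self.window_size}")
        if self.windows.shape[1] != self.window_size ** 2:
            raise ValueError("window rows must hold M^2 positions")


@dataclass
class AttentionMask:
    """Per-window additive bias: 0 for same-region pairs, MASK_VALUE otherwise."""

    bias: np.ndarray             # (n_windows, M^2, M^2)


@dataclass
class AttentionParams:
    """Weights of one windowed multi-head self-attention layer.

    Projections act on row vectors: ``q = x @ wq`` etc.  The relative
    position bias table has one learnable scalar per head for each of the
    ``(2M-1)^2`` possible in-window offsets; ``rel_bias_table`` may be
    ``None`` to disable the bias.
    """

    num_heads: int
    wq: np.ndarray               # (C, C)
    wk: np.ndarray
    wv: np.ndarray
    wo: np.ndarray
    rel_bias_table: np.ndarray | None = None   # ((2M-1)^2, num_heads)
    bq: np.ndarray | None = None
    bk: np.ndarray | None = None
    bv: np.ndarray | None = None
    bo: np.ndarray | None = None


def _padded_size(n: int, m: int) -> int:
    return ((n + m - 1) // m) * m


def pad_to_multiple(x: np.ndarray, m: int) -> np.ndarray:
    """Reflect-pad the trailing two axes of (..., h, w) up to multiples of m.

    Reflection requires the pad width to be smaller than the axis length;
    for degenerate maps smaller than that, periodic (wrap) padding is used
    instead so that every shape can still be partitioned.
    """
    h, w = x.shape[-2], x.shape[-1]
    ph, pw = _padded_size(h, m) - h, _padded_size(w, m) - w
    if ph == 0 and pw == 0:
        return x
    pad = [(0, 0)] * (x.ndim - 2) + [(0, ph), (0, pw)]
    mode = "reflect" if (ph < h and pw < w) else "wrap"
    return np.pad(x, pad, mode=mode)


def _split(x: np.ndarray, m: int) -> np.ndarray:
    """(N, hp, wp) -> (N * n_windows, m*m) raster-order tiles."""
    N, hp, wp = x.shape
    t = x.reshape(N, hp // m, m, wp // m, m).transpose(0, 1, 3, 2, 4)
    return np.ascontiguousarray(t).reshape(N * (hp // m) * (wp // m), m * m)


def _join(wins: np.ndarray, N: int, hp: int, wp: int, m: int) -> np.ndarray:
    """Inverse of :func:`_split`."""
    t = wins.reshape(N, hp // m, wp // m, m, m).transpose(0, 1, 3, 2, 4)
    return np.ascontiguousarray(t).reshape(N, hp, wp)


def partition_windows(feat: np.ndarray, window_size: int, shift: int = 0) -> WindowSet:
    """Split a (C, h, w) feature map into flat M x M attention windows.

    The map is reflect-padded up to multiples of ``window_size``, cyclically
    rolled by ``-shift`` along both spatial axes, and cut into raster-order
    tiles.  ``merge_windows`` inverts the operation exactly.
    """
    feat = np.asarray(feat)
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if feat.ndim != 3 or feat.size == 0:
        raise ValueError("feature map must be a non-empty (C, h, w) array")
    if not 0 <= shift < window_size:
        raise ValueError("shift must lie in [0, window_size)")
    C, h, w = feat.shape
    x = pad_to_multiple(feat, window_size)
    if shift:
        x = np.roll(x, (-shift, -shift), axis=(1, 2))
    wins = _split(x, window_size)                      # (C * nW, M^2)
    nw = wins.shape[0] // C
    wins = wins.reshape(C, nw, window_size ** 2).transpose(1, 2, 0)
    return WindowSet(np.ascontiguousarray(wins), (h, w), window_size, shift)


def merge_windows(ws: WindowSet) -> np.ndarray:
    """Reassemble a WindowSet into its (C, h, w) feature map (exact inverse)."""
    h, w = ws.origin_shape
    m = ws.window_size
    hp, wp = _padded_size(h, m), _padded_size(w, m)
    nw, t, C = ws.windows.shape
    wins = np.ascontiguousarray(ws.windows.transpose(2, 0, 1)).reshape(C * nw, t)
    x = _join(wins, C, hp, wp, m)
    if ws.shift:
        x = np.roll(x, (ws.shift, ws.shift), axis=(1, 2))
    return x[:, :h, :w]


def region_labels(h: int, w: int, window_size: int, shift: int) -> np.ndarray:
    """Pre-shift region label of every position of the padded, shifted grid.

    After a cyclic shift by ``-shift``, each spatial axis of the shifted map
    decomposes into three bands that originate from different parts of the
    unshifted map; the 3 x 3 products of those bands get distinct labels.
    Tokens with different labels were not neighbours before the shift and
    must not attend to each other.
    """
    m = window_size
    hp, wp = _padded_size(h, m), _padded_size(w, m)
    labels = np.zeros((hp, wp), dtype=np.int64)
    if shift == 0:
        return labels
    bands = (slice(0, -m), slice(-m, -shift), slice(-shift, None))
    cnt = 0
    for hs in bands:
        for ws_ in bands:
            labels[hs, ws_] = cnt
            cnt += 1
    return labels


def build_shift_mask(h: int, w: int, window_size: int, shift: int) -> AttentionMask:
    """Additive attention mask for a cyclically shifted window partition.

    With ``shift == 0`` the mask is all zeros.  Otherwise entry
    ``(win, a, b)`` is ``MASK_VALUE`` exactly when positions ``a`` and ``b``
    of window ``win`` carry different pre-shift region labels.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if not 0 <= shift < window_size:
        raise ValueError("shift must lie in [0, window_size)")
    m = window_size
    hp, wp = _padded_size(h, m), _padded_size(w, m)
    n_windows = (hp // m) * (wp // m)
    if shift == 0:
        return AttentionMask(np.zeros((n_windows, m * m, m * m), dtype=nn.DEFAULT_DTYPE))
    labels = region_labels(h, w, m, shift)
    win_labels = _split(labels[None], m)              # (n_windows, M^2)
    diff = win_labels[:, :, None] != win_labels[:, None, :]
    return AttentionMask(np.where(diff, MASK_VALUE, 0.0).astype(nn.DEFAULT_DTYPE))


def relative_position_index(window_size: int) -> np.ndarray:
    """(M^2, M^2) index into the (2M-1)^2 relative position bias table."""
    m = window_size
    coords = np.stack(np.meshgrid(np.arange(m), np.arange(m), indexing="ij"), axis=0)
    coords = coords.reshape(2, -1)                    # (2, M^2)
    rel = coords[:, :, None] - coords[:, None, :]     # (2, M^2, M^2)
    rel = rel + (m - 1)
    return rel[0] * (2 * m - 1) + rel[1]


def attention_core(tokens, qkv_w, qkv_b, proj_w, proj_b, num_heads,
                   bias=None):
    """Forward pass of multi-head self-attention over flat windows.

    tokens: (NW, T, C); qkv_w: (3C, C) applied as ``tokens @ qkv_w.T``;
    bias: (nb, num_heads, T, T) additive logit bias (relative position bias
    plus shift mask, already combined) with NW a multiple of nb — it is
    broadcast over the leading batch — or None.
    Returns (out, cache) where cache feeds :func:`attention_core_backward`.
    """
    NW, T, C = tokens.shape
    if C % num_heads != 0:
        raise ValueError(f"channels {C} not divisible by num_heads {num_heads}")
    dh = C // num_heads
    scale = 1.0 / np.sqrt(dh)
    qkv = tokens.reshape(-1, C) @ qkv_w.T
    if qkv_b is not None:
        qkv += qkv_b
    qkv = np.ascontiguousarray(
        qkv.reshape(NW, T, 3, num_heads, dh).transpose(2, 0, 3, 1, 4))
    q, k, v = qkv[0], qkv[1], qkv[2]                  # (NW, nh, T, dh)
    scores = (q @ k.swapaxes(-1, -2)) * scale
    if bias is not None:
        scores.reshape(NW // bias.shape[0], bias.shape[0], num_heads, T, T)[...] += bias
    # stabilised softmax, in place
    scores -= scores.max(axis=-1, keepdims=True)
    np.exp(scores, out=scores)
    scores /= scores.sum(axis=-1, keepdims=True)
    attn = scores
    ctx = attn @ v
    ctx = np.ascontiguousarray(ctx.transpose(0, 2, 1, 3)).reshape(NW, T, C)
    out = ctx.reshape(-1, C) @ proj_w.T
    if proj_b is not None:
        out += proj_b
    out = out.reshape(NW, T, C)
    cache = (tokens, q, k, v, attn, ctx, qkv_w, proj_w, num_heads)
    return out, cache


def attention_core_backward(dout, cache):
    """Backward pass of :func:`attention_core`.

    Returns (dtokens, d_qkv_w, d_qkv_b, d_proj_w, d_proj_b, d_rel_bias)
    where ``d_rel_bias`` has shape (num_heads, T, T) (sum over windows).
    """
    tokens, q, k, v, attn, ctx, qkv_w, proj_w, num_heads = cache
    NW, T, C = tokens.shape
    dh = C // num_heads
    scale = 1.0 / np.sqrt(dh)
    doutf = dout.reshape(-1, C)
    d_proj_w = doutf.T @ ctx.reshape(-1, C)
    d_proj_b = doutf.sum(axis=0)
    dctx = (doutf @ proj_w).reshape(NW, T, C)
    dctx = dctx.reshape(NW, T, num_heads, dh).transpose(0, 2, 1, 3)
    dattn = dctx @ v.swapaxes(-1, -2)
    dv = attn.swapaxes(-1, -2) @ dctx
    # softmax backward
    dscores = (dattn - np.sum(dattn * attn, axis=-1, keepdims=True)) * attn
    d_rel_bias = dscores.sum(axis=0)
    dq = (dscores @ k) * scale
    dk = dscores.swapaxes(-1, -2) @ q * scale
    dqkv = np.stack([dq, dk, dv])                     # (3, NW, nh, T, dh)
    dqkv = np.ascontiguousarray(dqkv.transpose(1, 3, 0, 2, 4)).reshape(NW * T, 3 * C)
    d_qkv_w = dqkv.T @ tokens.reshape(-1, C)
    d_qkv_b = dqkv.sum(axis=0)
    dtokens = (dqkv @ qkv_w).reshape(NW, T, C)
    return dtokens, d_qkv_w, d_qkv_b, d_proj_w, d_proj_b, d_rel_bias


def window_msa(ws: WindowSet, params: AttentionParams,
               mask: AttentionMask | None = None) -> WindowSet:
    """Multi-head self-attention applied independently inside each window.

    Per window and head: ``softmax(Q K^T / sqrt(d_head) + bias + mask) V``,
    heads concatenated and output-projected.  Shape is preserved.
    """
    wins = ws.windows
    NW, T, C = wins.shape
    if C % params.num_heads != 0:
        raise ValueError("channel count must be divisible by num_heads")
    for name in ("wq", "wk", "wv", "wo"):
        if not np.all(np.isfinite(getattr(params, name))):
            raise RuntimeError(f"non-finite attention weights in {name}")
    qkv_w = np.concatenate([params.wq.T, params.wk.T, params.wv.T], axis=0)
    if any(b is not None for b in (params.bq, params.bk, params.bv)):
        zeros = np.zeros(C, dtype=wins.dtype)
        qkv_b = np.concatenate([
            params.bq if params.bq is not None else zeros,
            params.bk if params.bk is not None else zeros,
            params.bv if params.bv is not None else zeros,
        ])
    else:
        qkv_b = None
    bias = None
    if params.rel_bias_table is not None:
        m = ws.window_size
        idx = relative_position_index(m)
        bias = params.rel_bias_table[idx].transpose(2, 0, 1)[None]  # (1, nh, T, T)
    if mask is not None:
        masked = mask.bias[:, None]                                 # (nW, 1, T, T)
        bias = masked if bias is None else bias + masked
    out, _ = attention_core(wins, qkv_w, qkv_b, params.wo.T, params.bo,
                            params.num_heads, bias)
    if not np.all(np.isfinite(out)):
        raise RuntimeError("non-finite attention output")
    return WindowSet(out, ws.origin_shape, ws.window_size, ws.shift)


class WindowMSA(nn.Module):
    """Trainable windowed multi-head self-attention layer.

    Operates on already-partitioned token windows ``(NW, T, C)``; the
    owning layer handles partitioning, shifting and masking geometry.
    """

    def __init__(self, dim, num_heads, window_size, rng, use_rel_bias=True,
                 dtype=nn.DEFAULT_DTYPE):
        if dim % num_heads != 0:
            raise ValueError("embed dim must be divisible by num_heads")
        self.dim = dim
        self.num_heads = num_heads
        self.window_size = window_size
        self.qkv_w = nn.Parameter(nn.trunc_normal(rng, (3 * dim, dim), dtype=dtype))
        self.qkv_b = nn.Parameter(np.zeros(3 * dim, dtype=dtype))
        self.proj_w = nn.Parameter(nn.trunc_normal(rng, (dim, dim), dtype=dtype))
        self.proj_b = nn.Parameter(np.zeros(dim, dtype=dtype))
        self.use_rel_bias = use_rel_bias
        if use_rel_bias:
            n_offsets = (2 * window_size - 1) ** 2
            self.rel_bias_table = nn.Parameter(
                nn.trunc_normal(rng, (n_offsets, num_heads), dtype=dtype))
            self._rel_index = relative_position_index(window_size)
        self._cache = None

    def forward(self, wins: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        bias = None
        if self.use_rel_bias:
            bias = self.rel_bias_table.data[self._rel_index].transpose(2, 0, 1)[None]
        if mask is not None:
            masked = mask[:, None]
            bias = masked if bias is None else bias + masked
        out, cache = attention_core(wins, self.qkv_w.data, self.qkv_b.data,
                                    self.proj_w.data, self.proj_b.data,
                                    self.num_heads, bias)
        self._cache = cache
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dtok, dqkv_w, dqkv_b, dproj_w, dproj_b, drel = \
            attention_core_backward(dout, self._cache)
        self._cache = None
        self.qkv_w.grad += dqkv_w
        self.qkv_b.grad += dqkv_b
        self.proj_w.grad += dproj_w
        self.proj_b.grad += dproj_b
        if self.use_rel_bias:
            np.add.at(self.rel_bias_table.grad,
                      self._rel_index.reshape(-1),
                      np.ascontiguousarray(drel.transpose(1, 2, 0)).reshape(-1, self.num_heads))
        return dtok
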
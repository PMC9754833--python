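"""MSE/PSNR image-quality metrics and the model-vs-baseline harness.

PSNR is computed as ``10 * log10(MaxValue^2 / MSE)`` with
``MaxValue = 2**bits - 1`` and the MSE taken over all pixels (channels
pooled).  Identical images give an MSE of zero and are reported with a
``+inf`` sentinel rather than an error.  Evaluation degrades each held-out
HR image, super-resolves the LR copy (with the model or the bicubic
baseline), optionally crops a border of ``scale`` pixels — boundary pixels
are dominated by interpolation edge effects — and scores against the HR
reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import (Image, bicubic_resize, center_crop_to_multiple, degrade,
                   read_image, read_manifest)


def _as_array(x):
    return x.data if isinstance(x, Image) else np.asarray(x)


def mse(j, l) -> float:
    """Mean squared difference over all positions (and channels)."""
    j, l = _as_array(j), _as_array(l)
    if j.shape != l.shape:
        raise ValueError(f"shape mismatch {j.shape} vs {l.shape}")
    d = j.astype(np.float64) - l.astype(np.float64)
    return float(np.mean(d * d))


def psnr(j, l, bits: int = 8) -> float:
    """Peak signal-to-noise ratio in dB between images on [0, 1].

    ``10 * log10(MaxValue^2 / MSE)`` on the ``[0, 2**bits - 1]`` scale;
    returns ``inf`` when the images are identical.
    """
    if bits < 1:
        raise ValueError("bits must be >= 1")
    maxv = 2.0 ** bits - 1.0
    m = mse(_as_array(j) * maxv, _as_array(l) * maxv)
    if m == 0:
        return float("inf")
    return float(10.0 * np.log10(maxv * maxv / m))


@dataclass
class EvalResult:
    per_image: list                # (id, mse, psnr_dB) triples
    aggregate: float               # mean over finite per-image PSNRs
    scale: int
    method_label: str
    manifest: str = ""

    @property
    def n_images(self):
        return len(self.per_image)


def bicubic_upscale(lr: Image, scale: int) -> Image:
    """The baseline: plain bicubic interpolation back to HR size."""
    return bicubic_resize(lr, lr.height * scale, lr.width * scale)


def _aggregate(per_image):
    finite = [p for _, _, p in per_image if np.isfinite(p)]
    return float(np.mean(finite)) if finite else float("inf")


def evaluate(method, manifest_path, scale: int, split: str = "test",
             border: int | None = None, errors: list | None = None) -> EvalResult:
    """Score a super-resolution method on one split of a dataset manifest.

    ``method`` is the string ``"bicubic"`` or a model with a ``forward``
    accepting a ``(C, h, w)`` array (its ``config.in_channels`` is honoured
    by channel replication for grayscale sources).  I/O failures are
    recorded per file in ``errors`` (if given) and evaluation continues.
    """
    entries = [e for e in read_manifest(manifest_path) if e["split"] == split]
    if not entries:
        raise ValueError(f"split {split!r} of {manifest_path} is empty")
    crop = scale if border is None else border
    per_image = []
    label = method if isinstance(method, str) else "model"
    for e in entries:
        try:
            hr = center_crop_to_multiple(read_image(e["path"]), scale)
            lr = degrade(hr, scale)
            if method == "bicubic":
                sr = bicubic_upscale(lr, scale)
            else:
                x = lr.data
                want = method.config.in_channels
                if want == 3 and x.shape[0] == 1:
                    x = np.repeat(x, 3, axis=0)
                y = method.forward(x)
                if want == 3 and hr.channels == 1:
                    y = y.mean(axis=0, keepdims=True)
                sr = Image(np.clip(y, 0.0, 1.0), hr.bits)
            a, b = sr.data, hr.data
            if crop:
                a = a[:, crop:-crop, crop:-crop]
                b = b[:, crop:-crop, crop:-crop]
            m = mse(a * hr.value_range, b * hr.value_range)
            p = float("inf") if m == 0 else float(
                10.0 * np.log10(hr.value_range ** 2 / m))
            per_image.append((str(e["path"]), m, p))
        except (OSError, ValueError) as exc:   # unreadable file: record, continue
            if errors is not None:
                errors.append((str(e["path"]), str(exc)))
    return EvalResult(per_image, _aggregate(per_image), scale, label,
                      str(manifest_path))


def psnr_delta(a: EvalResult, b: EvalResult) -> float:
    """Aggregate-PSNR improvement of method a over method b (dB)."""
    if a.manifest != b.manifest or a.scale != b.scale:
        raise ValueError("results come from different manifests or scales")
    return a.aggregate - b.aggregate
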
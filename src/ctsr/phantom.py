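"""Synthetic CT-slice phantoms.

Real CT slices mix large flat regions (organ interiors), strong
high-contrast boundaries (bone, body outline) and mild texture/noise.  The
phantoms here reproduce exactly that dichotomy so the low-frequency versus
high-frequency split the network architecture is built around is actually
present in the test data: an elliptical body on a smooth background
gradient, a bright bone-like ring along the body outline, several interior
"organ" ellipses at distinct intensity levels, a low-frequency sinusoidal
texture and optional Gaussian noise.  No attempt is made at physical CT
simulation (no projection geometry, no beam hardening).

Generation is pure in (spec, seed): the same inputs always produce the
same image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import Image, SplitSpec, write_image, write_manifest


@dataclass
class PhantomSpec:
    """Parameters of the phantom family.

    ``intensity_levels`` are the mean intensities of the interior organ
    ellipses (cycled if ``n_organs`` exceeds the list).  ``edge_contrast``
    is the intensity step from body to bone ring; ``noise_sd`` and
    ``texture_amplitude`` control the stochastic fine structure.
    """

    size: int = 128
    n_organs: int = 4
    intensity_levels: tuple = (0.2, 0.5, 0.62, 0.75)
    edge_contrast: float = 0.45
    noise_sd: float = 0.01
    texture_amplitude: float = 0.03
    body_level: float = 0.35
    background_level: float = 0.05

    def __post_init__(self):
        if self.size < 32:
            raise ValueError("phantom size must be >= 32")
        if not 0 <= self.noise_sd < 0.2:
            raise ValueError("noise_sd must lie in [0, 0.2)")
        if self.texture_amplitude < 0:
            raise ValueError("texture_amplitude must be >= 0")
        for lv in self.intensity_levels:
            if not 0.0 <= lv <= 1.0:
                raise ValueError("intensity levels must lie in [0, 1]")
        if self.n_organs < 0:
            raise ValueError("n_organs must be >= 0")


def _ellipse_mask(yy, xx, cy, cx, ay, ax, theta):
    """Boolean mask of a rotated ellipse on normalized [-1, 1] coordinates."""
    c, s = np.cos(theta), np.sin(theta)
    u = (yy - cy) * c + (xx - cx) * s
    v = -(yy - cy) * s + (xx - cx) * c
    return (u / ay) ** 2 + (v / ax) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec, seed: int) -> Image:
    """Render one phantom slice as a single-channel image on [0, 1]."""
    rng = np.random.default_rng(seed)
    n = spec.size
    ax1d = np.linspace(-1.0, 1.0, n, dtype=np.float64)
    yy, xx = np.meshgrid(ax1d, ax1d, indexing="ij")

    # smooth low-frequency background gradient
    gx, gy = rng.uniform(-0.03, 0.03, size=2)
    img = spec.background_level + gx * xx + gy * yy

    # body ellipse with a bright ring along its outline
    body_ay = rng.uniform(0.72, 0.85)
    body_ax = rng.uniform(0.72, 0.85)
    body_th = rng.uniform(0, np.pi)
    ring_width = 0.07
    body = _ellipse_mask(yy, xx, 0.0, 0.0, body_ay, body_ax, body_th)
    inner = _ellipse_mask(yy, xx, 0.0, 0.0, body_ay - ring_width,
                          body_ax - ring_width, body_th)
    img[body] = spec.body_level
    ring_level = min(0.95, spec.body_level + spec.edge_contrast)
    img[body & ~inner] = ring_level

    # interior organs at distinct mean intensities
    for i in range(spec.n_organs):
        level = spec.intensity_levels[i % len(spec.intensity_levels)]
        cy, cx = rng.uniform(-0.35, 0.35, size=2)
        ay = rng.uniform(0.08, 0.28)
        ax_ = rng.uniform(0.08, 0.28)
        th = rng.uniform(0, np.pi)
        organ = _ellipse_mask(yy, xx, cy, cx, ay, ax_, th) & inner
        img[organ] = level

    # bandlimited texture: sum of three low-frequency sinusoids
    if spec.texture_amplitude > 0:
        tex = np.zeros_like(img)
        for _ in range(3):
            fy, fx = rng.uniform(1.0, 4.0, size=2)
            phase = rng.uniform(0, 2 * np.pi)
            tex += np.sin(np.pi * (fy * yy + fx * xx) + phase)
        img = img + spec.texture_amplitude * tex / 3.0

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    return Image(np.clip(img, 0.0, 1.0).astype(np.float32), bits=16)


def generate_dataset(n: int, spec: PhantomSpec, seed: int, out_dir,
                     split: SplitSpec | None = None) -> Path:
    """Write n distinct phantoms plus a train/val/test manifest.

    Per-image seeds derive from ``seed``; the split follows the 20 : 2 : 1
    train : validation : test ratio unless another :class:`SplitSpec` is
    given.  Returns the manifest path.
    """
    if n < 1:
        raise ValueError("need at least one phantom")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    split = split or SplitSpec(seed=seed)
    labels = split.assign(n)
    child_seeds = np.random.default_rng(seed).integers(0, 2 ** 31, size=n)
    rows = []
    for i in range(n):
        img = generate_phantom(spec, int(child_seeds[i]))
        name = f"phantom_{i:04d}.png"
        write_image(img, out_dir / name)
        rows.append((name, labels[i], img.height, img.width, img.bits))
    manifest = out_dir / "manifest.csv"
    write_manifest(rows, manifest)
    return manifest
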
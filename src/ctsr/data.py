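"""Image I/O, bicubic degradation, paired patch extraction and augmentation.

Training pairs are manufactured, not collected: a high-resolution (HR)
image is bicubically downsampled by the scale factor to produce its
low-resolution (LR) counterpart, and the network learns the inverse map.
Intensities are held in float32 on [0, 1] internally; the original bit
depth travels with the image so peak signal-to-noise ratios use the right
``MaxValue``.

The bicubic dialect is Pillow's: Catmull-Rom (a = -0.5) with an antialias
prefilter whenever the image is shrunk.  Resizer implementations differ in
exactly this choice, so the dialect string is recorded in run provenance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

BICUBIC_DIALECT = "pillow-catmull-rom-a0.5-antialias"


@dataclass
class Image:
    """A raster image: (C, H, W) float32 on [0, 1] plus its source bit depth."""

    data: np.ndarray
    bits: int = 8

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3 or self.data.shape[0] not in (1, 3):
            raise ValueError("image data must be (H, W), (1, H, W) or (3, H, W)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values")

    @property
    def value_range(self) -> int:
        return 2 ** self.bits - 1

    @property
    def channels(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]


@dataclass
class PatchPair:
    """An aligned LR/HR training patch; HR dims are exactly LR dims x r."""

    lr: Image
    hr: Image
    source_id: str = ""
    top_left: tuple = (0, 0)    # HR-space (row, col), 0-based

    def __post_init__(self):
        rh = self.hr.height / self.lr.height
        rw = self.hr.width / self.lr.width
        if rh != rw or rh != int(rh):
            raise ValueError("HR dims must be an integer multiple of LR dims")

    @property
    def scale(self) -> int:
        return self.hr.height // self.lr.height


@dataclass
class SplitSpec:
    """Disjoint, exhaustive train/validation/test partition of an image list."""

    ratio: tuple = (20, 2, 1)   # train : validation : test
    seed: int = 0

    def assign(self, n: int) -> list:
        """Split labels for n items: proportional counts (largest remainder),
        shuffled assignment, reproducible from the seed."""
        total = sum(self.ratio)
        raw = [n * r / total for r in self.ratio]
        counts = [int(np.floor(x)) for x in raw]
        remainders = np.argsort([c - x for c, x in zip(counts, raw)])
        for i in range(n - sum(counts)):
            counts[remainders[i]] += 1
        labels = (["train"] * counts[0] + ["val"] * counts[1] + ["test"] * counts[2])
        order = np.random.default_rng(self.seed).permutation(n)
        out = [None] * n
        for slot, idx in enumerate(order):
            out[idx] = labels[slot]
        return out


# --- resampling ---------------------------------------------------------

def bicubic_resize(img: Image, out_h: int, out_w: int) -> Image:
    """Bicubic (Catmull-Rom) resampling with antialiasing on downscale.

    Channels are resampled independently; output is clipped to [0, 1].
    """
    if out_h < 1 or out_w < 1:
        raise ValueError("target size must be at least 1x1")
    chans = []
    for c in range(img.channels):
        pil = PILImage.fromarray(img.data[c], mode="F")
        chans.append(np.asarray(pil.resize((out_w, out_h), PILImage.Resampling.BICUBIC),
                                dtype=np.float32))
    return Image(np.clip(np.stack(chans), 0.0, 1.0), img.bits)


def center_crop_to_multiple(img: Image, r: int) -> Image:
    """Center-crop so both spatial dims are divisible by r."""
    h, w = img.height, img.width
    nh, nw = (h // r) * r, (w // r) * r
    if nh < 1 or nw < 1:
        raise ValueError(f"image {h}x{w} smaller than factor {r}")
    top, left = (h - nh) // 2, (w - nw) // 2
    return Image(img.data[:, top:top + nh, left:left + nw], img.bits)


def degrade(hr: Image, scale: int) -> Image:
    """HR -> LR by bicubic downsampling; crops to a multiple of scale first."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    hr = center_crop_to_multiple(hr, scale)
    return bicubic_resize(hr, hr.height // scale, hr.width // scale)


# --- patch sampling and augmentation ------------------------------------

def sample_patch_pair(hr: Image, lr: Image, p: int, r: int,
                      rng) -> PatchPair:
    """Uniformly random LR-aligned patch pair: LR p x p, HR (p*r) x (p*r).

    ``rng`` is an integer seed or a ``numpy.random.Generator``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if lr.height < p or lr.width < p:
        raise ValueError(f"LR image {lr.height}x{lr.width} smaller than patch {p}")
    if hr.height != lr.height * r or hr.width != lr.width * r:
        raise ValueError("HR dims must equal LR dims times the scale")
    top = int(rng.integers(0, lr.height - p + 1))
    left = int(rng.integers(0, lr.width - p + 1))
    lr_patch = Image(lr.data[:, top:top + p, left:left + p], lr.bits)
    hr_patch = Image(hr.data[:, top * r:(top + p) * r, left * r:(left + p) * r], hr.bits)
    return PatchPair(lr_patch, hr_patch, top_left=(top * r, left * r))


def dihedral_transform(data: np.ndarray, k: int) -> np.ndarray:
    """Element k of the dihedral-8 group on a (C, H, W) array:
    k % 4 quarter-turns, then a horizontal flip if k >= 4."""
    out = np.rot90(data, k % 4, axes=(1, 2))
    if k >= 4:
        out = out[:, :, ::-1]
    return np.ascontiguousarray(out)


def augment(pair: PatchPair, rng) -> PatchPair:
    """Apply one of the 8 dihedral transforms (uniform) to both members."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    k = int(rng.integers(0, 8))
    return PatchPair(Image(dihedral_transform(pair.lr.data, k), pair.lr.bits),
                     Image(dihedral_transform(pair.hr.data, k), pair.hr.bits),
                     pair.source_id, pair.top_left)


# --- file I/O -----------------------------------------------------------

def read_image(path) -> Image:
    """Read an 8/16-bit grayscale or 8-bit RGB PNG/TIFF into [0, 1] floats."""
    path = Path(path)
    with PILImage.open(path) as pil:
        pil.load()
        mode = pil.mode
        if mode == "L":
            arr, bits = np.asarray(pil, dtype=np.float32)[None], 8
        elif mode in ("I;16", "I;16B", "I"):
            arr = np.asarray(pil, dtype=np.float32)[None]
            bits = 16
        elif mode == "RGB":
            arr = np.asarray(pil, dtype=np.float32).transpose(2, 0, 1)
            bits = 8
        else:
            raise ValueError(f"unsupported image mode {mode!r} in {path}")
    return Image(arr / (2 ** bits - 1), bits)


def write_image(img: Image, path):
    """Write losslessly as PNG/TIFF at the image's bit depth."""
    path = Path(path)
    maxv = img.value_range
    q = np.round(np.clip(img.data, 0.0, 1.0) * maxv)
    if img.channels == 3:
        if img.bits != 8:
            raise ValueError("RGB output supports 8-bit depth only")
        pil = PILImage.fromarray(q.transpose(1, 2, 0).astype(np.uint8), mode="RGB")
    elif img.bits == 8:
        pil = PILImage.fromarray(q[0].astype(np.uint8), mode="L")
    elif img.bits == 16:
        pil = PILImage.fromarray(q[0].astype(np.uint16))
    else:
        raise ValueError(f"unsupported bit depth {img.bits} for {path}")
    pil.save(path)


# --- dataset manifests --------------------------------------------------

MANIFEST_COLUMNS = ("path", "split", "h", "w", "bits")


def write_manifest(rows, path):
    """rows: iterables of (path, split, h, w, bits); written as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        writer.writerows(rows)


def read_manifest(path) -> list:
    """Read a dataset manifest; image paths resolve relative to the CSV."""
    base = Path(path).parent
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if tuple(reader.fieldnames) != MANIFEST_COLUMNS:
            raise ValueError(f"bad manifest header in {path}")
        for row in reader:
            p = Path(row["path"])
            out.append({"path": p if p.is_absolute() else base / p,
                        "split": row["split"],
                        "h": int(row["h"]), "w": int(row["w"]),
                        "bits": int(row["bits"])})
    return out
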
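"""Seeded generator of histology-like patches with exact ground truth.

Patches emulate stained tissue at toy scale: a background ("Other")
field on which elliptical regions of the remaining tissue classes are
stamped in class order (later classes overwrite earlier ones). The image
is the per-pixel class mean colour plus Gaussian texture noise, clipped
to [0, 1]; the mask is the stamped class map, so ground truth is exact
by construction. Detection labels are tied to the presence of at least
one tumor-class region, which makes the mask modality perfectly
predictive of the label.

An optional texture-only mode gives every class the same mean colour and
distinguishes classes solely by their noise standard deviation; there
the class signal lives in texture rather than colour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as _ellipse

from .mask_codec import LabelMask, TissuePatch

__all__ = [
    "FixtureSpec",
    "SegmentationDataset",
    "generate_tissue_patch",
    "generate_segmentation_dataset",
    "generate_detection_dataset",
    "TUMOR_CLASS",
    "DEFAULT_PALETTE",
]

TUMOR_CLASS = 1  # class index whose presence defines a "cancer" patch

# per-class mean RGB, loosely following H&E appearance:
# other (pale pink), tumor (dense purple), stroma (pink), inflammation
# (dark blue), necrosis (pale eosinophilic)
DEFAULT_PALETTE = np.array([
    [0.87, 0.78, 0.83],
    [0.45, 0.28, 0.55],
    [0.91, 0.57, 0.66],
    [0.25, 0.28, 0.55],
    [0.80, 0.72, 0.55],
])
DEFAULT_NOISE_SD = 0.06


@dataclass
class FixtureSpec:
    """Parameters of the synthetic patch generator.

    ``blob_count`` and ``blob_radius`` give, per foreground class
    1..K−1, the inclusive range of ellipse counts and semi-axis lengths
    (pixels). Defaults scale with patch size.
    """

    size: int = 16
    K: int = 3
    n: int = 200
    cancer_fraction: float = 0.5
    palette: np.ndarray | None = None
    noise_sd: np.ndarray | float = DEFAULT_NOISE_SD
    blob_count: tuple[int, int] = (0, 2)  # classes may be absent from a patch
    blob_radius: tuple[float, float] | None = None
    texture_only: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.size < 8:
            raise ValueError(f"size must be >= 8, got {self.size}")
        if not (2 <= self.K <= 8):
            raise ValueError(f"K must be in 2..8, got {self.K}")
        if not (0.0 <= self.cancer_fraction <= 1.0):
            raise ValueError(f"cancer_fraction must lie in [0, 1], got {self.cancer_fraction}")
        if self.palette is None:
            if self.texture_only:
                self.palette = np.tile([[0.6, 0.5, 0.6]], (self.K, 1))
            elif self.K <= len(DEFAULT_PALETTE):
                self.palette = DEFAULT_PALETTE[: self.K].copy()
            else:
                rng = np.random.default_rng(1234)
                self.palette = rng.uniform(0.1, 0.9, (self.K, 3))
        self.palette = np.asarray(self.palette, dtype=np.float64)
        if self.palette.shape != (self.K, 3):
            raise ValueError(f"palette must be ({self.K}, 3), got {self.palette.shape}")
        sd = np.asarray(self.noise_sd, dtype=np.float64)
        if sd.ndim == 0:
            if self.texture_only:
                # class-graded texture: background smooth, classes noisier
                sd = float(sd) * (1.0 + 1.5 * np.arange(self.K))
            else:
                sd = np.full(self.K, float(sd))
        if sd.shape != (self.K,):
            raise ValueError(f"noise_sd must be scalar or length-{self.K}")
        self.noise_sd = sd
        if self.blob_radius is None:
            self.blob_radius = (self.size / 8.0, self.size / 4.0)


@dataclass
class SegmentationDataset:
    train: list
    val: list
    test: list
    class_pixel_freq: np.ndarray = field(repr=False, default=None)


def _stamp_class(mask: np.ndarray, cls: int, spec: FixtureSpec,
                 rng: np.random.Generator, n_blobs: int) -> None:
    H = spec.size
    r_lo, r_hi = spec.blob_radius
    for _ in range(n_blobs):
        a = rng.uniform(r_lo, r_hi)
        b = rng.uniform(r_lo, r_hi)
        margin = min(max(a, b), (H - 1) / 2.0)
        cy = rng.uniform(margin, H - 1 - margin)
        cx = rng.uniform(margin, H - 1 - margin)
        rot = rng.uniform(0.0, np.pi)
        rr, cc = _ellipse(cy, cx, a, b, shape=(H, H), rotation=rot)
        mask[rr, cc] = cls


def generate_tissue_patch(spec: FixtureSpec, rng: np.random.Generator,
                          force_tumor: bool | None = None) -> TissuePatch:
    """One patch: stamped ellipse mask plus colour/texture rendering.

    ``force_tumor`` pins the tumor class to present (True) or absent
    (False); None lets the blob-count range decide (counts may be 0 when
    the range includes 0).
    """
    H = spec.size
    mask = np.zeros((H, H), dtype=np.int64)
    c_lo, c_hi = spec.blob_count
    for cls in range(1, spec.K):
        n_blobs = int(rng.integers(c_lo, c_hi + 1))
        if cls == TUMOR_CLASS and force_tumor is not None:
            n_blobs = max(n_blobs, 1) if force_tumor else 0
        _stamp_class(mask, cls, spec, rng, n_blobs)
    image = spec.palette[mask]  # H×W×3 class means
    sd = spec.noise_sd[mask][..., None]
    image = np.clip(image + rng.normal(0.0, 1.0, image.shape) * sd, 0.0, 1.0)
    label = "cancer" if np.any(mask == TUMOR_CLASS) else "normal"
    return TissuePatch(image=image, mask=LabelMask(labels=mask, K=spec.K), label=label)


def generate_segmentation_dataset(spec: FixtureSpec,
                                  rng: np.random.Generator | None = None,
                                  fractions=(0.7, 0.15, 0.15)) -> SegmentationDataset:
    """Disjoint seeded train/val/test splits with a class-frequency report."""
    if spec.n < 3:
        raise ValueError(f"need n >= 3 patches to split, got {spec.n}")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    patches = [generate_tissue_patch(spec, rng) for _ in range(spec.n)]
    n_train = max(1, int(round(spec.n * fractions[0])))
    n_val = max(1, int(round(spec.n * fractions[1])))
    n_val = min(n_val, spec.n - n_train - 1)
    train = patches[:n_train]
    val = patches[n_train:n_train + n_val]
    test = patches[n_train + n_val:]
    freq = np.zeros(spec.K, dtype=np.float64)
    for p in patches:
        freq += np.bincount(p.mask.labels.ravel(), minlength=spec.K)
    freq /= freq.sum()
    return SegmentationDataset(train=train, val=val, test=test, class_pixel_freq=freq)


def generate_detection_dataset(spec: FixtureSpec,
                               rng: np.random.Generator | None = None):
    """n labelled patches with exactly round(n·cancer_fraction) cancers.

    Cancer patches contain at least one tumor-class region; normal
    patches contain none (other foreground classes occur in both).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n_cancer = int(round(spec.n * spec.cancer_fraction))
    flags = np.array([True] * n_cancer + [False] * (spec.n - n_cancer))
    rng.shuffle(flags)
    out = []
    for flag in flags:
        # a forced tumor blob can be fully overwritten by a later class;
        # redraw (deterministically, from the same stream) until it survives
        for _ in range(100):
            patch = generate_tissue_patch(spec, rng, force_tumor=bool(flag))
            if (patch.label == "cancer") == bool(flag):
                break
        else:
            raise RuntimeError("could not realise the requested tumor presence")
        out.append((patch, patch.label))
    return out
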
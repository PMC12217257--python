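"""Label-mask containers and the bidirectional mapping between integer
tissue masks and the continuous space the diffusion model operates in.

A mask with K tissue classes is encoded one-hot over K channels and
rescaled to {−1, +1} (label k → +1 on channel k, −1 elsewhere), so that
per-channel Gaussian corruption treats every class symmetrically and
decoding is a per-pixel argmax. Masks travel on disk as single-channel
8-bit PNGs whose pixel value is the class index.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "LabelMask",
    "EncodedMask",
    "TissuePatch",
    "encode_mask",
    "decode_mask",
    "read_mask_png",
    "write_mask_png",
    "read_image",
    "write_image_png",
    "TISSUE_CLASS_NAMES",
]

# canonical five-class tissue legend (class index -> name)
TISSUE_CLASS_NAMES = ("Other", "Tumor", "Stroma", "Inflammation", "Necrosis")


@dataclass(frozen=True)
class LabelMask:
    """An H×W integer tissue map with values in 0..K−1."""

    labels: np.ndarray
    K: int

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 2 or labels.size == 0:
            raise ValueError(f"labels must be a non-empty H×W map, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            labels = labels.astype(np.int64)
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if labels.min() < 0 or labels.max() >= self.K:
            raise ValueError(
                f"labels must lie in 0..{self.K - 1}, found range "
                f"[{labels.min()}, {labels.max()}]")
        object.__setattr__(self, "labels", labels.astype(np.int64))

    @property
    def shape(self):
        return self.labels.shape


@dataclass(frozen=True)
class EncodedMask:
    """H×W×K real-valued encoding of a label mask, values in [−1, 1]."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"values must be H×W×K, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("encoded mask contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def K(self) -> int:
        return self.values.shape[2]


@dataclass
class TissuePatch:
    """An RGB patch with optional ground-truth mask and detection label.

    ``image`` is H×W×3 float in [0, 1]; ``label`` is "normal"/"cancer"
    when present.
    """

    image: np.ndarray
    mask: LabelMask | None = None
    label: str | None = None

    def __post_init__(self):
        img = np.asarray(self.image, dtype=np.float64)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"image must be H×W×3, got shape {img.shape}")
        if self.mask is not None and self.mask.shape != img.shape[:2]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match image {img.shape[:2]}")
        if self.label is not None and self.label not in ("normal", "cancer"):
            raise ValueError(f"label must be 'normal' or 'cancer', got {self.label!r}")
        self.image = img


def encode_mask(mask: LabelMask) -> EncodedMask:
    """One-hot encode to K channels in {−1, +1}."""
    H, W = mask.shape
    values = -np.ones((H, W, mask.K), dtype=np.float64)
    rows, cols = np.indices((H, W))
    values[rows, cols, mask.labels] = 1.0
    return EncodedMask(values=values)


def decode_mask(encoded: EncodedMask | np.ndarray) -> LabelMask:
    """Per-pixel argmax over channels; ties go to the lowest class index."""
    values = encoded.values if isinstance(encoded, EncodedMask) else np.asarray(encoded)
    if values.ndim != 3:
        raise ValueError(f"expected H×W×K values, got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("cannot decode non-finite channel values")
    labels = np.argmax(values, axis=2)  # numpy argmax returns the first maximum
    return LabelMask(labels=labels, K=values.shape[2])


# ---------------------------------------------------------------------------
# PNG round trips
# ---------------------------------------------------------------------------

def write_mask_png(mask: LabelMask, path, legend_path=None) -> None:
    """Write class indices as 8-bit grayscale; optional sidecar legend."""
    Image.fromarray(mask.labels.astype(np.uint8), mode="L").save(str(path))
    if legend_path is not None:
        names = TISSUE_CLASS_NAMES[:mask.K] if mask.K <= len(TISSUE_CLASS_NAMES) else [
            f"class_{i}" for i in range(mask.K)]
        lines = [f"{i}\t{name}" for i, name in enumerate(names)]
        Path(legend_path).write_text("\n".join(lines) + "\n")


def read_mask_png(path, K: int) -> LabelMask:
    arr = np.asarray(Image.open(str(path)).convert("L"), dtype=np.int64)
    return LabelMask(labels=arr, K=K)


def write_image_png(image: np.ndarray, path) -> None:
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8), mode="RGB").save(str(path))


def read_image(path) -> np.ndarray:
    """Read an RGB image (PNG/TIFF/...) to H×W×3 float in [0, 1]."""
    arr = np.asarray(Image.open(str(path)).convert("RGB"), dtype=np.float64)
    return arr / 255.0
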
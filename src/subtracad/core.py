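"""Shared containers for the temporal-subtraction pipeline.

All images are 2D float64 arrays on the internal intensity scale [0, 1];
conversion to/from the stored bit depth happens only at I/O boundaries.
Geometry is 0-based, row-major; bounding boxes are half-open
``(row0, col0, row1, col1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

VIEWS = ("CC", "MLO")
ROUNDS = ("prior", "recent")
DENSITY_CLASSES = ("a", "b", "c", "d")


class SubtracadError(Exception):
    """Base class for pipeline errors."""


class DegenerateGeometryError(SubtracadError):
    """Raised when a synthetic mass cannot be placed inside the breast."""


class SegmentationFailureError(SubtracadError):
    """Raised when no breast foreground can be found in an image."""


@dataclass
class Mammogram:
    """One 2D grayscale mammographic view with acquisition metadata."""

    pixels: np.ndarray
    patient_id: str = ""
    view: str = "CC"
    round: str = "recent"
    pixel_spacing: Optional[float] = None  # mm / pixel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D image, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("image contains negative pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "Mammogram":
        return replace(self, pixels=np.asarray(pixels, dtype=np.float64))


@dataclass
class DeformationField:
    """Dense per-pixel displacement ``u`` with ``warped(x) = moving(x + u(x))``.

    ``displacement`` has shape ``(2, rows, cols)``: channel 0 is the row
    offset, channel 1 the column offset, both in pixels.
    """

    displacement: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        if self.displacement.ndim != 3 or self.displacement.shape[0] != 2:
            raise ValueError("displacement must have shape (2, rows, cols)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.displacement.shape[1:]

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.displacement[0], self.displacement[1])

    def __neg__(self) -> "DeformationField":
        return DeformationField(-self.displacement, provenance=self.provenance)


@dataclass
class ResidualImage:
    """Nonnegative temporal-subtraction residual (recent − warped prior)."""

    pixels: np.ndarray
    breast_mask: np.ndarray
    patient_id: str = ""
    view: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.breast_mask = np.asarray(self.breast_mask, dtype=bool)
        if self.pixels.shape != self.breast_mask.shape:
            raise ValueError("residual and mask shapes differ")


@dataclass
class CandidateROI:
    """A connected candidate region segmented from the residual."""

    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    patient_id: str = ""
    view: str = ""
    area_px: int = 0
    matched_truth: Optional[str] = None  # None | "benign" | "malignant"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.area_px = int(self.mask.sum())


@dataclass
class FeatureVector:
    """Ordered feature record for one ROI with stable names."""

    values: np.ndarray
    names: tuple[str, ...]
    patient_id: str = ""
    view: str = ""
    roi_id: int = -1
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.names),):
            raise ValueError("values/names length mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def as_mask(arr: np.ndarray, shape: Optional[tuple[int, int]] = None) -> np.ndarray:
    """Validate and coerce a binary mask."""
    mask = np.asarray(arr, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    if shape is not None and mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} != expected {shape}")
    return mask
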
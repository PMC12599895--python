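"""The fixed 98-feature catalog extracted from each candidate ROI.

Composition (order frozen, names stable across runs):

* 72 GLCM texture features — statistics {correlation, contrast, energy,
  homogeneity} × distances {D1=1, D2=2, D3=4 px} × angle slots
  {0°, 45°, 90°, 135°, Mean, STD over the four angles}.  The co-occurrence
  matrix is computed symmetric and normalized on ROI pixels quantized to
  16 gray levels over the ROI min–max, restricted to the ROI mask.
* 10 first-order statistics of the intensity histogram — mean, STD,
  variance, skewness, kurtosis, entropy (bits, 64-bin), energy, median,
  1st and 99th percentiles.
* 4 intensity features — maximum, mean, minimum, range.
* 12 shape features of the ROI mask — area, perimeter, major/minor axis
  length, eccentricity, orientation, equivalent diameter, extent, convex
  area, filled area, solidity, circularity 4πA/P².

Degenerate conventions: a constant ROI (single quantized level) yields
correlation 0, contrast 0, energy 1, homogeneity 1, FOS entropy 0 and
energy 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from skimage import measure
from skimage.feature import graycomatrix

from .core import CandidateROI, FeatureVector

GLCM_STATISTICS = ("correlation", "contrast", "energy", "homogeneity")
GLCM_ANGLE_SLOTS = ("0", "45", "90", "135", "mean", "std")
GLCM_ANGLES_RAD = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)

FOS_NAMES = (
    "fos_mean",
    "fos_std",
    "fos_variance",
    "fos_skewness",
    "fos_kurtosis",
    "fos_entropy",
    "fos_energy",
    "fos_median",
    "fos_p01",
    "fos_p99",
)
INTENSITY_NAMES = ("int_max", "int_mean", "int_min", "int_range")
SHAPE_NAMES = (
    "shape_area",
    "shape_perimeter",
    "shape_major_axis_length",
    "shape_minor_axis_length",
    "shape_eccentricity",
    "shape_orientation",
    "shape_equivalent_diameter",
    "shape_extent",
    "shape_convex_area",
    "shape_filled_area",
    "shape_solidity",
    "shape_circularity",
)


@dataclass
class GLCMSpec:
    distances: tuple[int, int, int] = (1, 2, 4)
    levels: int = 16

    def __post_init__(self) -> None:
        if list(self.distances) != sorted(set(self.distances)):
            raise ValueError("distances must be strictly increasing")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")


def glcm_feature_names(spec: GLCMSpec | None = None) -> tuple[str, ...]:
    spec = spec or GLCMSpec()
    names = []
    for stat in GLCM_STATISTICS:
        for d_index in range(len(spec.distances)):
            for slot in GLCM_ANGLE_SLOTS:
                names.append(f"glcm_{stat}_{slot}_d{d_index + 1}")
    return tuple(names)


FEATURE_NAMES: tuple[str, ...] = (
    glcm_feature_names() + FOS_NAMES + INTENSITY_NAMES + SHAPE_NAMES
)
N_FEATURES = len(FEATURE_NAMES)  # 98


def _quantize(pixels: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Quantize masked pixels to 1..levels; background stays 0."""
    out = np.zeros(pixels.shape, dtype=np.uint8)
    vals = pixels[mask]
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        out[mask] = 1
        return out
    q = np.floor((pixels - lo) / (hi - lo) * levels).astype(int)
    out[mask] = np.clip(q[mask], 0, levels - 1) + 1
    return out


def _glcm_stats(p: np.ndarray) -> dict[str, float]:
    """Haralick statistics of one normalized symmetric GLCM (levels×levels)."""
    total = p.sum()
    if total <= 0:
        return {"correlation": 0.0, "contrast": 0.0, "energy": 1.0, "homogeneity": 1.0}
    p = p / total
    levels = p.shape[0]
    i = np.arange(levels, dtype=np.float64)[:, None]
    j = np.arange(levels, dtype=np.float64)[None, :]
    mu_i = (i * p).sum()
    mu_j = (j * p).sum()
    var_i = (((i - mu_i) ** 2) * p).sum()
    var_j = (((j - mu_j) ** 2) * p).sum()
    contrast = (((i - j) ** 2) * p).sum()
    energy = (p**2).sum()
    homogeneity = (p / (1.0 + (i - j) ** 2)).sum()
    if var_i <= 1e-15 or var_j <= 1e-15:
        correlation = 0.0  # zero-variance convention
    else:
        correlation = (((i - mu_i) * (j - mu_j) * p).sum()) / np.sqrt(var_i * var_j)
    return {
        "correlation": float(correlation),
        "contrast": float(contrast),
        "energy": float(energy),
        "homogeneity": float(homogeneity),
    }


def glcm_features(
    pixels: np.ndarray, mask: np.ndarray, spec: GLCMSpec | None = None
) -> dict[str, float]:
    """All 72 GLCM features of the masked ROI."""
    spec = spec or GLCMSpec()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    quant = _quantize(np.asarray(pixels, dtype=np.float64), mask, spec.levels)
    glcm = graycomatrix(
        quant,
        distances=list(spec.distances),
        angles=list(GLCM_ANGLES_RAD),
        levels=spec.levels + 1,
        symmetric=True,
        normed=False,
    )
    out: dict[str, float] = {}
    for d_index in range(len(spec.distances)):
        per_angle: dict[str, list[float]] = {s: [] for s in GLCM_STATISTICS}
        for a_index, slot in enumerate(GLCM_ANGLE_SLOTS[:4]):
            # drop co-occurrences with the background level 0
            p = glcm[1:, 1:, d_index, a_index].astype(np.float64)
            vals = _glcm_stats(p)
            for stat in GLCM_STATISTICS:
                per_angle[stat].append(vals[stat])
                out[f"glcm_{stat}_{slot}_d{d_index + 1}"] = vals[stat]
        for stat in GLCM_STATISTICS:
            arr = np.asarray(per_angle[stat])
            out[f"glcm_{stat}_mean_d{d_index + 1}"] = float(arr.mean())
            out[f"glcm_{stat}_std_d{d_index + 1}"] = float(arr.std())
    return out


def fos_features(pixels: np.ndarray, mask: np.ndarray, n_bins: int = 64) -> dict[str, float]:
    """First-order statistics of the masked intensity histogram."""
    vals = np.asarray(pixels, dtype=np.float64)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty ROI mask")
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        hist, _ = np.histogram(vals, bins=n_bins, range=(lo, hi))
        p = hist / hist.sum()
        p = p[p > 0]
        entropy = float(-(p * np.log2(p)).sum())
        energy = float((p**2).sum())
        skew = float(sstats.skew(vals))
        kurt = float(sstats.kurtosis(vals))
    else:
        entropy, energy, skew, kurt = 0.0, 1.0, 0.0, 0.0
    return {
        "fos_mean": float(vals.mean()),
        "fos_std": float(vals.std()),
        "fos_variance": float(vals.var()),
        "fos_skewness": skew,
        "fos_kurtosis": kurt,
        "fos_entropy": entropy,
        "fos_energy": energy,
        "fos_median": float(np.median(vals)),
        "fos_p01": float(np.percentile(vals, 1)),
        "fos_p99": float(np.percentile(vals, 99)),
    }


def intensity_features(pixels: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    vals = np.asarray(pixels, dtype=np.float64)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty ROI mask")
    return {
        "int_max": float(vals.max()),
        "int_mean": float(vals.mean()),
        "int_min": float(vals.min()),
        "int_range": float(vals.max() - vals.min()),
    }


def shape_features(mask: np.ndarray, pixel_spacing: float | None = None) -> dict[str, float]:
    """Geometry of the ROI mask; lengths in pixels (or mm if spacing given)."""
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    if labels.max() != 1:
        raise ValueError("ROI mask must be a single connected component")
    region = measure.regionprops(labels)[0]
    s = pixel_spacing if pixel_spacing else 1.0
    perimeter = max(region.perimeter, 1e-12)
    circularity = 4.0 * np.pi * region.area / perimeter**2
    return {
        "shape_area": float(region.area * s * s),
        "shape_perimeter": float(region.perimeter * s),
        "shape_major_axis_length": float(region.axis_major_length * s),
        "shape_minor_axis_length": float(region.axis_minor_length * s),
        "shape_eccentricity": float(region.eccentricity),
        "shape_orientation": float(region.orientation),
        "shape_equivalent_diameter": float(region.equivalent_diameter_area * s),
        "shape_extent": float(region.extent),
        "shape_convex_area": float(region.area_convex * s * s),
        "shape_filled_area": float(region.area_filled * s * s),
        "shape_solidity": float(region.solidity),
        "shape_circularity": float(circularity),
    }


def extract_all(
    roi: CandidateROI,
    image: np.ndarray,
    spec: GLCMSpec | None = None,
    pixel_spacing: float | None = None,
    roi_id: int = -1,
) -> FeatureVector:
    """The full ordered 98-value feature vector for one ROI."""
    pixels = np.asarray(image, dtype=np.float64)
    if pixels.shape != roi.mask.shape:
        raise ValueError("image and ROI mask shapes differ")
    values = {}
    values.update(glcm_features(pixels, roi.mask, spec))
    values.update(fos_features(pixels, roi.mask))
    values.update(intensity_features(pixels, roi.mask))
    values.update(shape_features(roi.mask, pixel_spacing))
    vec = np.array([values[name] for name in FEATURE_NAMES])
    if not np.all(np.isfinite(vec)):
        bad = [n for n, v in zip(FEATURE_NAMES, vec) if not np.isfinite(v)]
        raise ValueError(f"non-finite features: {bad}")
    return FeatureVector(
        vec,
        FEATURE_NAMES,
        patient_id=roi.patient_id,
        view=roi.view,
        roi_id=roi_id,
        label=roi.matched_truth,
    )


_SHAPE_LOOKUP = {
    "major axis length": "shape_major_axis_length",
    "minor axis length": "shape_minor_axis_length",
    "perimeter": "shape_perimeter",
    "area": "shape_area",
    "equivalent diameter": "shape_equivalent_diameter",
    "extent": "shape_extent",
    "convex area": "shape_convex_area",
    "filled area": "shape_filled_area",
    "circularity": "shape_circularity",
    "solidity": "shape_solidity",
    "eccentricity": "shape_eccentricity",
    "orientation": "shape_orientation",
}


def resolve_feature_name(name: str) -> str:
    """Map a human/report-style feature name onto the frozen catalog.

    Accepts e.g. ``"Correlation 90° D2"``, ``"Correlation Mean D1"``,
    ``"Correlation STD D2"``, ``"Maximum intensity"``, ``"STD"`` (FOS),
    ``"Solidity"``.  Raises ``KeyError`` for unknown names.
    """
    cleaned = re.sub(r"\$[^$]*\$", " ", name)  # drop TeX degree markup
    for token in ("\\circ", "°", "^", "{", "}"):
        cleaned = cleaned.replace(token, " ")
    cleaned = re.sub(r"\s+", " ", cleaned).strip().lower()

    if cleaned in FEATURE_NAMES:
        return cleaned
    if cleaned in _SHAPE_LOOKUP:
        return _SHAPE_LOOKUP[cleaned]
    if cleaned == "std":
        return "fos_std"
    if cleaned in ("maximum intensity", "max intensity"):
        return "int_max"
    if cleaned == "mean intensity":
        return "int_mean"
    if cleaned in ("minimum intensity", "min intensity"):
        return "int_min"
    if cleaned == "intensity range":
        return "int_range"

    m = re.match(r"(correlation|contrast|energy|homogeneity) (0|45|90|135|mean|std) d([1-9])", cleaned)
    if m:
        candidate = f"glcm_{m.group(1)}_{m.group(2)}_d{m.group(3)}"
        if candidate in FEATURE_NAMES:
            return candidate
    raise KeyError(f"unknown feature name: {name!r}")
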
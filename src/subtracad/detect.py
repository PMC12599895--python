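"""Candidate-mass segmentation from the subtraction residual.

Three steps: percentile thresholding of the nonzero residual, morphological
cleanup (opening, hole filling, small-object removal), and removal of
peripheral components near the skin line, where registration edge effects
concentrate.  Surviving connected components become candidate ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes, distance_transform_edt
from skimage import filters, measure, morphology

from .core import CandidateROI, ResidualImage, as_mask


@dataclass
class DetectParams:
    threshold_method: str = "otsu"  # "otsu" | "percentile"
    threshold_percentile: float = 87.0
    close_radius: int = 2
    open_radius: int = 1
    min_area: int = 40
    peripheral_margin: int = 12


def threshold_residual(res: ResidualImage, q: float = 97.0) -> np.ndarray:
    """Foreground = residual pixels ≥ the q-th percentile of nonzero
    residual values inside the breast mask."""
    if not 0 < q < 100:
        raise ValueError("percentile q must be in (0, 100)")
    values = res.pixels[res.breast_mask & (res.pixels > 0)]
    if values.size == 0:
        return np.zeros(res.pixels.shape, dtype=bool)
    cutoff = np.percentile(values, q)
    return (res.pixels >= cutoff) & res.breast_mask & (res.pixels > 0)


def threshold_residual_otsu(res: ResidualImage) -> np.ndarray:
    """Foreground by an Otsu split of the nonzero residual values.

    Unlike a fixed percentile, the cutoff adapts to the lesion load: a
    residual carrying several bright masses still separates them from the
    noise floor instead of rationing a fixed pixel budget.
    """
    values = res.pixels[res.breast_mask & (res.pixels > 0)]
    if values.size == 0 or np.ptp(values) == 0:
        return np.zeros(res.pixels.shape, dtype=bool)
    cutoff = filters.threshold_otsu(values)
    return (res.pixels >= cutoff) & res.breast_mask


def morph_clean(
    mask: np.ndarray,
    open_radius: int = 1,
    min_area: int = 40,
    close_radius: int = 2,
) -> np.ndarray:
    """Closing (reconnects fragmented spiculated responses), opening,
    hole filling, small-component removal."""
    if open_radius < 0 or close_radius < 0:
        raise ValueError("radii must be >= 0")
    out = as_mask(mask)
    if close_radius > 0:
        out = morphology.closing(out, morphology.disk(close_radius))
    if open_radius > 0:
        out = morphology.opening(out, morphology.disk(open_radius))
    out = binary_fill_holes(out)
    if min_area > 0:
        # keep components with area >= min_area
        labels = measure.label(out, connectivity=2)
        for region in measure.regionprops(labels):
            if region.area < min_area:
                out[labels == region.label] = False
    return out


def remove_peripheral(mask: np.ndarray, breast, margin: int = 12) -> np.ndarray:
    """Discard components whose centroid lies within ``margin`` pixels of
    the breast boundary."""
    if margin < 0:
        raise ValueError("margin must be >= 0")
    out = as_mask(mask).copy()
    if margin == 0 or not out.any():
        return out
    breast = as_mask(breast, out.shape)
    depth = distance_transform_edt(breast)
    labels = measure.label(out, connectivity=2)
    for region in measure.regionprops(labels):
        r, c = (int(round(x)) for x in region.centroid)
        r = min(max(r, 0), out.shape[0] - 1)
        c = min(max(c, 0), out.shape[1] - 1)
        if depth[r, c] <= margin:
            out[labels == region.label] = False
    return out


def label_candidates(mask: np.ndarray, res: ResidualImage) -> list[CandidateROI]:
    """8-connected labeling; one ROI per component, largest first."""
    mask = as_mask(mask, res.pixels.shape)
    labels = measure.label(mask, connectivity=2)
    rois = []
    for region in measure.regionprops(labels):
        rois.append(
            CandidateROI(
                mask=labels == region.label,
                bbox=tuple(region.bbox),
                centroid=tuple(region.centroid),
                patient_id=res.patient_id,
                view=res.view,
            )
        )
    rois.sort(key=lambda r: -r.area_px)
    return rois


def segment_candidates(res: ResidualImage, params: DetectParams | None = None) -> list[CandidateROI]:
    """Full three-step segmentation: threshold → clean → de-peripheral."""
    params = params or DetectParams()
    if params.threshold_method == "otsu":
        mask = threshold_residual_otsu(res)
    else:
        mask = threshold_residual(res, params.threshold_percentile)
    mask = morph_clean(mask, params.open_radius, params.min_area, params.close_radius)
    mask = remove_peripheral(mask, res.breast_mask, params.peripheral_margin)
    return label_candidates(mask, res)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter / union) if union else 0.0


def match_to_truth(
    rois: list[CandidateROI],
    truth_masks: list[np.ndarray],
    truth_labels: list[str],
    iou_threshold: float = 0.1,
) -> dict:
    """Greedy best-IoU matching of candidates to ground-truth masses.

    Each ROI is matched to at most one truth mass (and vice versa);
    annotates ``roi.matched_truth`` in place and returns a tally with
    ``n_truth``, ``n_detected``, ``n_missed``, ``n_fp``.
    """
    if len(truth_masks) != len(truth_labels):
        raise ValueError("one label per truth mask required")
    pairs = []
    for i, roi in enumerate(rois):
        roi.matched_truth = None
        for j, tmask in enumerate(truth_masks):
            score = iou(roi.mask, tmask)
            if score >= iou_threshold:
                pairs.append((score, i, j))
    pairs.sort(reverse=True)
    used_roi: set[int] = set()
    used_truth: set[int] = set()
    for score, i, j in pairs:
        if i in used_roi or j in used_truth:
            continue
        rois[i].matched_truth = truth_labels[j]
        used_roi.add(i)
        used_truth.add(j)
    n_truth = len(truth_masks)
    n_detected = len(used_truth)
    return {
        "n_truth": n_truth,
        "n_detected": n_detected,
        "n_missed": n_truth - n_detected,
        "n_fp": len(rois) - len(used_roi),
    }
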
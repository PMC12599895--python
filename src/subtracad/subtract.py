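"""Temporal subtraction and its enhancement metrics.

Subtracting the registered prior from the recent view cancels anatomy that
is unchanged between screening rounds; newly developed or denser tissue
survives as a bright residual.  Negative differences (structure present in
the prior but not the recent image) are clipped to zero: the clinically
relevant signal here is new tissue, which is brighter in the recent round.
"""

from __future__ import annotations

import numpy as np

from .core import Mammogram, ResidualImage, as_mask


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, Mammogram) else np.asarray(img, dtype=np.float64)


def temporal_subtract(recent, warped_prior, mask) -> ResidualImage:
    """``max(recent − warped_prior, 0)`` inside the breast mask, 0 outside."""
    recent_px = _pixels(recent)
    prior_px = _pixels(warped_prior)
    if recent_px.shape != prior_px.shape:
        raise ValueError("recent and warped prior shapes differ")
    breast = as_mask(mask, recent_px.shape)
    residual = np.clip(recent_px - prior_px, 0.0, None) * breast
    meta = {}
    if isinstance(recent, Mammogram):
        meta = {"patient_id": recent.patient_id, "view": recent.view}
    return ResidualImage(residual, breast, **meta)


def contrast_ratio(img, lesion_mask, background_mask, eps: float = 1e-6) -> float:
    """Mean intensity over the lesion divided by mean over the background."""
    pixels = _pixels(img)
    lesion = as_mask(lesion_mask, pixels.shape)
    background = as_mask(background_mask, pixels.shape)
    if not lesion.any() or not background.any():
        raise ValueError("lesion and background masks must be nonempty")
    if (lesion & background).any():
        raise ValueError("lesion and background masks must be disjoint")
    return float(pixels[lesion].mean() / max(pixels[background].mean(), eps))


def background_reduction(before, after, background_mask) -> float:
    """Percent drop of mean background intensity: 100·(1 − after/before)."""
    before_px = _pixels(before)
    after_px = _pixels(after)
    background = as_mask(background_mask, before_px.shape)
    if not background.any():
        raise ValueError("background mask must be nonempty")
    mean_before = before_px[background].mean()
    if mean_before <= 0:
        raise ValueError("undefined metric: zero mean background before subtraction")
    return float(100.0 * (1.0 - after_px[background].mean() / mean_before))
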
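"""Deformable (Demons) and affine registration of prior onto recent views.

The prior mammogram of a screening pair is the *moving* image and the
recent one the *fixed* image.  Demons registration estimates a dense
displacement field ``u`` with ``warped(x) = moving(x + u(x))``; a 6-parameter
affine registration is kept as the rigid-er baseline for comparison.  Both
run through SimpleITK with a multiresolution schedule.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates

from .core import DeformationField, Mammogram

DEFAULT_ITERATIONS = (100, 50, 25)
DEFAULT_SHRINKS = (4, 2, 1)
DEFAULT_SMOOTHING_SIGMA = 3.0


def _to_pixels(img) -> np.ndarray:
    if isinstance(img, Mammogram):
        return img.pixels
    return np.asarray(img, dtype=np.float64)


def warp(img, field: DeformationField) -> np.ndarray:
    """Resample ``img`` through ``field`` (backward mapping, linear interp).

    ``out[r, c] = img[r + u_r(r, c), c + u_c(r, c)]``; samples falling
    outside the image domain evaluate to 0.
    """
    pixels = _to_pixels(img)
    if field.shape != pixels.shape:
        raise ValueError(f"field shape {field.shape} != image shape {pixels.shape}")
    rr, cc = np.meshgrid(
        np.arange(pixels.shape[0], dtype=np.float64),
        np.arange(pixels.shape[1], dtype=np.float64),
        indexing="ij",
    )
    coords = np.stack([rr + field.displacement[0], cc + field.displacement[1]])
    return map_coordinates(pixels, coords, order=1, mode="constant", cval=0.0)


def _sitk_from(arr: np.ndarray) -> sitk.Image:
    return sitk.GetImageFromArray(np.ascontiguousarray(arr, dtype=np.float64))


def _field_to_numpy(field_img: sitk.Image) -> np.ndarray:
    # SimpleITK stores (x, y) = (col, row) vector components
    arr = sitk.GetArrayFromImage(field_img)
    return np.stack([arr[..., 1], arr[..., 0]])


def _resample_field(field_img: sitk.Image, reference: sitk.Image) -> sitk.Image:
    return sitk.Resample(
        field_img,
        reference,
        sitk.Transform(),
        sitk.sitkLinear,
        0.0,
        field_img.GetPixelID(),
    )


def _shrink(img: sitk.Image, factor: int) -> sitk.Image:
    if factor == 1:
        return img
    smoothed = sitk.SmoothingRecursiveGaussian(img, factor / 2.0)
    return sitk.Shrink(smoothed, [factor, factor])


def mse(a, b) -> float:
    a = _to_pixels(a)
    b = _to_pixels(b)
    return float(np.mean((a - b) ** 2))


def demons_register(
    fixed,
    moving,
    iterations: Sequence[int] = DEFAULT_ITERATIONS,
    smoothing_sigma: float = DEFAULT_SMOOTHING_SIGMA,
    shrink_factors: Sequence[int] = DEFAULT_SHRINKS,
    histogram_match: bool = True,
) -> tuple[np.ndarray, DeformationField]:
    """Symmetric-forces Demons with Gaussian field smoothing, coarse-to-fine.

    The moving histogram is matched to the fixed one first: Demons assumes
    brightness constancy, and screening rounds differ by gain drift and by
    the adaptive equalization applied per image.

    Parameters
    ----------
    iterations
        Per-level iteration counts, coarsest level first.
    smoothing_sigma
        Gaussian standard deviation (pixels) applied to the displacement
        field each iteration.
    shrink_factors
        Pyramid shrink factor per level, matching ``iterations``.
    histogram_match
        Match the moving intensity histogram to the fixed image before
        estimating forces.

    Returns
    -------
    warped : ndarray
        Moving image resampled through the recovered field.
    field : DeformationField
        Recovered displacement, full-frame.

    Notes
    -----
    The recovered field is guaranteed not to increase the mean squared
    difference to the fixed image: if the Demons solution is worse than no
    registration at all (pathological inputs), the identity field is
    returned instead.
    """
    fixed_np = _to_pixels(fixed)
    moving_np = _to_pixels(moving)
    if fixed_np.shape != moving_np.shape:
        raise ValueError("fixed and moving images must share a shape")
    if len(iterations) != len(shrink_factors):
        raise ValueError("iterations and shrink_factors must align per level")

    fixed_img = _sitk_from(fixed_np)
    moving_img = _sitk_from(moving_np)
    if histogram_match:
        moving_img = sitk.HistogramMatching(moving_img, fixed_img, 256, 7)

    field_img: Optional[sitk.Image] = None
    for n_iter, factor in zip(iterations, shrink_factors):
        f_level = _shrink(fixed_img, factor)
        m_level = _shrink(moving_img, factor)
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(n_iter))
        demons.SetSmoothDisplacementField(True)
        demons.SetStandardDeviations(float(smoothing_sigma))
        if field_img is None:
            field_img = demons.Execute(f_level, m_level)
        else:
            init = _resample_field(field_img, f_level)
            field_img = demons.Execute(f_level, m_level, init)
    assert field_img is not None
    field_img = _resample_field(field_img, fixed_img)

    field = DeformationField(
        _field_to_numpy(field_img),
        provenance=f"demons(iterations={tuple(iterations)}, sigma={smoothing_sigma})",
    )
    warped = warp(moving_np, field)
    if mse(fixed_np, warped) > mse(fixed_np, moving_np):
        field = DeformationField(
            np.zeros((2, *fixed_np.shape)), provenance=field.provenance + " [identity fallback]"
        )
        warped = moving_np.copy()
    return warped, field


def affine_register(
    fixed,
    moving,
    iterations: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """6-parameter (2D affine) intensity-based registration baseline.

    Minimizes the dense mean-squared difference with LBFGS over a 3-level
    pyramid, B-spline interpolation, moments initialization.  Returns the
    warped moving image and the affine parameters
    ``(a11, a12, a21, a22, t_col, t_row)``.
    """
    fixed_np = _to_pixels(fixed)
    moving_np = _to_pixels(moving)
    if fixed_np.shape != moving_np.shape:
        raise ValueError("fixed and moving images must share a shape")

    fixed_img = _sitk_from(fixed_np)
    moving_img = _sitk_from(moving_np)

    initial = sitk.CenteredTransformInitializer(
        fixed_img,
        moving_img,
        sitk.AffineTransform(2),
        sitk.CenteredTransformInitializerFilter.MOMENTS,
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetOptimizerAsLBFGS2(numberOfIterations=int(iterations))
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2, 1, 0])
    reg.SetInitialTransform(initial, inPlace=False)
    reg.SetInterpolator(sitk.sitkBSpline)

    try:
        transform = reg.Execute(fixed_img, moving_img)
    except RuntimeError as exc:  # pragma: no cover - optimizer diagnostics
        raise RuntimeError(f"affine registration failed: {exc}") from exc

    warped_img = sitk.Resample(
        moving_img, fixed_img, transform, sitk.sitkBSpline, 0.0, sitk.sitkFloat64
    )
    warped = sitk.GetArrayFromImage(warped_img)
    params = np.asarray(transform.GetParameters(), dtype=np.float64)

    if mse(fixed_np, warped) > mse(fixed_np, moving_np):
        warped = moving_np.copy()
        params = np.array([1.0, 0.0, 0.0, 1.0, 0.0, 0.0])
    return warped, params
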
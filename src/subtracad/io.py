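"""Image and manifest I/O.

Images are stored as 16-bit PNG/TIFF (or read from DICOM); the internal
scale is float in [0, 1].  Masks are 8-bit PNG with foreground 255.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

UINT16_MAX = 65535


def write_image(path, pixels: np.ndarray) -> None:
    """Write a [0,1] float image as 16-bit grayscale."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, np.round(arr * UINT16_MAX).astype(np.uint16))


def write_mask(path, mask: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def read_image(path) -> np.ndarray:
    """Read PNG/TIFF/DICOM into a [0,1] float image."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float64)
    else:
        arr = iio.imread(path).astype(np.float64)
    if arr.ndim == 3:  # collapse accidental RGB
        arr = arr.mean(axis=2)
    peak = arr.max()
    if peak <= 0:
        return np.zeros_like(arr)
    # normalize by the representable range of the source dtype when known
    if peak <= 255:
        scale = 255.0
    elif peak <= UINT16_MAX:
        scale = float(UINT16_MAX)
    else:
        scale = peak
    return arr / scale


def read_mask(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return arr > arr.max() / 2 if arr.max() > 0 else arr.astype(bool)
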
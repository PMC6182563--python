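"""Calibrated micrograph I/O and preprocessing.

The preprocessing chain mirrors standard practice for phase-contrast
micrographs of mycelial objects: work in the green plane of the RGB image,
smooth with a small median filter (which preserves object size and shape),
then enhance object boundaries with a Sobel gradient-magnitude filter.
All downstream size measurements are converted to physical units through a
per-objective μm-per-pixel calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage as ndi

__all__ = [
    "CalibratedImage",
    "ImageLoadError",
    "load_image",
    "extract_green_plane",
    "median_smooth",
    "sobel_edge_magnitude",
]

# standard 3x3 Sobel kernel for the x (rightward, column) derivative;
# the y kernel is its transpose
_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])


class ImageLoadError(RuntimeError):
    """Raised when an image file cannot be read."""


@dataclass(frozen=True)
class CalibratedImage:
    """An intensity grid with a physical calibration.

    Parameters
    ----------
    pixels:
        2-D (grayscale) or (H, W, 3) RGB array. Stored as float64
        internally regardless of the source bit depth.
    calibration:
        Physical pixel size, μm per pixel (> 0). Areas are therefore
        ``n_pixels * calibration**2`` in μm².
    objective_id:
        Free-text identifier of the objective the frame was taken with.
    time_hr:
        Hours since inoculation, if known (≥ 0).
    condition:
        ``"standard"`` or ``"mpec"`` (microparticle-enhanced cultivation).
    """

    pixels: np.ndarray
    calibration: float
    objective_id: str = ""
    time_hr: Optional[float] = None
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim not in (2, 3):
            raise ValueError(f"pixels must be 2-D or 3-D, got ndim={px.ndim}")
        if px.ndim == 3 and px.shape[2] != 3:
            raise ValueError(
                f"3-D pixel grids must have 3 channels, got {px.shape[2]}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if not (self.calibration > 0):
            raise ValueError(
                f"calibration must be > 0 μm/px, got {self.calibration}"
            )
        if self.time_hr is not None and self.time_hr < 0:
            raise ValueError(f"time_hr must be ≥ 0, got {self.time_hr}")
        if self.condition is not None and self.condition not in ("standard", "mpec"):
            raise ValueError(
                f"condition must be 'standard' or 'mpec', got {self.condition!r}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3

    def with_pixels(self, pixels: np.ndarray) -> "CalibratedImage":
        """Copy of this image with the pixel grid replaced, metadata kept."""
        return replace(self, pixels=pixels)


def load_image(
    path: str | Path,
    calibration: float,
    *,
    objective_id: str = "",
    time_hr: Optional[float] = None,
    condition: Optional[str] = None,
) -> CalibratedImage:
    """Read a TIFF or PNG micrograph as a :class:`CalibratedImage`.

    8- and 16-bit, grayscale and RGB files are accepted; RGB channel order
    is preserved. Alpha channels are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise ImageLoadError(f"image file not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(str(path))
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except ImageLoadError:
        raise
    except Exception as exc:  # corrupt / unsupported file
        raise ImageLoadError(f"failed to read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return CalibratedImage(
        pixels=arr,
        calibration=calibration,
        objective_id=objective_id,
        time_hr=time_hr,
        condition=condition,
    )


def extract_green_plane(img: CalibratedImage) -> CalibratedImage:
    """Green channel of an RGB image; grayscale input is returned unchanged.

    The green plane carries the strongest, least chromatically biased
    contrast in phase-contrast RGB captures, so segmentation operates on it.
    """
    if not img.is_rgb:
        return img
    return img.with_pixels(img.pixels[:, :, 1])


def median_smooth(img: CalibratedImage, radius: int = 1) -> CalibratedImage:
    """Median filter over a (2·radius+1)² neighborhood, edges replicated.

    A small median kernel suppresses shot noise and ragged single-pixel
    boundary artifacts without changing object size or shape, which is why
    it precedes edge detection.
    """
    if img.is_rgb:
        raise ValueError("median_smooth expects a grayscale image; "
                         "apply extract_green_plane first")
    if radius < 1:
        raise ValueError(f"radius must be ≥ 1, got {radius}")
    size = 2 * int(radius) + 1
    out = ndi.median_filter(img.pixels, size=size, mode="nearest")
    return img.with_pixels(out)


def sobel_edge_magnitude(img: CalibratedImage) -> CalibratedImage:
    """Gradient magnitude sqrt(Gx² + Gy²) with the standard 3×3 Sobel kernels.

    Output is non-negative and invariant under adding a constant offset to
    the input, which makes the segmentation threshold independent of the
    absolute illumination level.
    """
    if img.is_rgb:
        raise ValueError("sobel_edge_magnitude expects a grayscale image")
    gx = ndi.convolve(img.pixels, _SOBEL_X, mode="nearest")
    gy = ndi.convolve(img.pixels, _SOBEL_X.T, mode="nearest")
    return img.with_pixels(np.hypot(gx, gy))
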
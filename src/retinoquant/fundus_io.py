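"""Reading, standardising and decomposing colour fundus photographs.

Conventions used throughout the package:

* A colour fundus photograph is a :class:`FundusImage`: an 8-bit RGB array of
  shape ``(height, width, 3)`` plus its source path.
* A *gray image* is a plain 2-D ``float64`` array with values in ``[0, 1]``;
  8-bit quantisation happens only at file boundaries.
* Coordinates are row-major, origin top-left, 0-based, ``(row, col)`` order.
* Binary masks are 2-D boolean arrays; on disk they are single-channel PNGs
  with 0 = background and 255 = foreground.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

#: Standardised working size (width, height) used for all quantification.
STANDARD_WIDTH = 685
STANDARD_HEIGHT = 584


class FormatError(ValueError):
    """Raised when a file decodes but is not a usable 8-bit raster."""


@dataclass(frozen=True)
class FundusImage:
    """An 8-bit RGB fundus photograph.

    Attributes
    ----------
    pixels:
        ``uint8`` array of shape ``(height, width, 3)``.
    source_path:
        Where the image came from (empty string for synthetic images).
    """

    pixels: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) pixels, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {px.dtype}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class PixelCalibration:
    """Physical scale of an image.

    Attributes
    ----------
    microns_per_pixel:
        Retinal microns imaged per pixel; must be positive.  At the
        standardised 685 x 584 size a 45-degree field of view corresponds to
        roughly 25 um/px.
    fov_degrees:
        Camera field of view, informational only.
    """

    microns_per_pixel: float
    fov_degrees: float = 45.0

    def __post_init__(self) -> None:
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be > 0")

    def rescaled(self, original_width: int, new_width: int) -> "PixelCalibration":
        """Calibration after resizing from ``original_width`` to ``new_width``."""
        return replace(
            self,
            microns_per_pixel=self.microns_per_pixel * (original_width / new_width),
        )


def read_image(path: str | Path) -> FundusImage:
    """Read an 8-bit RGB raster (PNG/TIFF/JPEG) as a :class:`FundusImage`.

    Grayscale files are replicated to three channels with a logged warning;
    an alpha channel, if present, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalise decoder errors
        raise FormatError(f"cannot decode {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit raster, got dtype {arr.dtype}")
    if arr.ndim == 2:
        logger.warning("%s is grayscale; replicating to 3 channels", path)
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: unsupported raster shape {arr.shape}")
    if path.suffix.lower() in {".jpg", ".jpeg"}:
        logger.warning(
            "%s is JPEG; compression artifacts can affect small-lesion detection", path
        )
    return FundusImage(pixels=arr, source_path=str(path))


def write_image(img: FundusImage | np.ndarray, path: str | Path) -> None:
    """Write an RGB image (or a [0, 1] gray array, rescaled to 8-bit)."""
    if isinstance(img, FundusImage):
        arr = img.pixels
    else:
        arr = np.asarray(img)
        if arr.dtype != np.uint8:
            arr = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask PNG (0 = background, nonzero = foreground)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return arr > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a 0/255 single-channel PNG."""
    iio.imwrite(Path(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def standardize(
    img: FundusImage,
    target_width: int = STANDARD_WIDTH,
    target_height: int = STANDARD_HEIGHT,
) -> FundusImage:
    """Resize to the standard working size (default 685 x 584) bilinearly.

    Aspect ratio is not preserved: the image is resampled to exactly the
    target grid.  The bilinear kernel support is scaled with the downscale
    factor (area-weighted averaging), so downscaling is alias-free and
    ringing-free — appropriate for area statistics.  Any attached
    :class:`PixelCalibration` must be updated with
    :meth:`PixelCalibration.rescaled` using the same width ratio.
    """
    if target_width < 1 or target_height < 1:
        raise ValueError("target dimensions must be >= 1")
    if (img.height, img.width) == (target_height, target_width):
        return img
    out = Image.fromarray(img.pixels).resize(
        (target_width, target_height), resample=Image.BILINEAR
    )
    return FundusImage(pixels=np.asarray(out), source_path=img.source_path)


def extract_green(img: FundusImage) -> np.ndarray:
    """Return the green channel rescaled to ``[0, 1]``.

    The green channel carries the strongest contrast between retinal tissue
    and both bright (exudate) and dark (vessel, microaneurysm) structures,
    which is why every detector in this package starts from it.
    """
    return img.pixels[:, :, 1].astype(np.float64) / 255.0
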
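"""Contrast enhancement shared by the exudate and microaneurysm detectors.

Three steps are provided:

* :func:`stretch_contrast` — luminance-compensated min-max stretch
  ``J = a * (I - I_min) / (I_max - I_min)``, clipped to ``[0, 1]``.
* :func:`adaptive_equalize` — contrast-limited adaptive histogram
  equalization (CLAHE) on a tile grid.
* :func:`top_bottom_hat_enhance` — ``g + tophat(g, b) - bottomhat(g, b)``,
  which simultaneously brightens small bright structures and darkens small
  dark structures relative to a disk structure element ``b``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.exposure import equalize_adapthist
from skimage.morphology import black_tophat, closing, opening, white_tophat
from skimage.morphology import disk as _disk

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnhanceParams:
    """Tunables for the enhancement stage.

    Attributes
    ----------
    a:
        Luminance compensation coefficient of the stretch; ``a = 1`` maps the
        intensity extremes onto ``[0, 1]`` exactly, ``a > 1`` saturates
        highlights.
    tile_grid:
        Tiles per axis for the adaptive equalization.
    clip_limit:
        CLAHE clipping limit as a fraction in ``(0, 1]``; limits noise
        amplification in flat regions.
    """

    a: float = 1.0
    tile_grid: int = 8
    clip_limit: float = 0.01

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("a must be > 0")
        if self.tile_grid < 1:
            raise ValueError("tile_grid must be >= 1")
        if not 0 < self.clip_limit <= 1:
            raise ValueError("clip_limit must be in (0, 1]")


@dataclass(frozen=True)
class StructureElement:
    """A discrete disk footprint ``{(dr, dc): dr^2 + dc^2 <= radius^2}``."""

    radius: int = 6
    shape: str = "disk"

    def __post_init__(self) -> None:
        if self.shape != "disk":
            raise ValueError("only disk elements are supported")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")

    @property
    def footprint(self) -> np.ndarray:
        return _disk(self.radius)


def _check_gray(gray: np.ndarray) -> np.ndarray:
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2 or gray.size == 0:
        raise ValueError("expected a nonempty 2-D gray image")
    return gray


def stretch_contrast(gray: np.ndarray, params: EnhanceParams = EnhanceParams()) -> np.ndarray:
    """Min-max stretch with luminance compensation, clipped to ``[0, 1]``.

    A constant image has no dynamic range to stretch; it is returned
    unchanged with a logged warning.
    """
    gray = _check_gray(gray)
    lo, hi = float(gray.min()), float(gray.max())
    if hi == lo:
        logger.warning("stretch_contrast: constant image, returned unchanged")
        return gray.copy()
    return np.clip(params.a * (gray - lo) / (hi - lo), 0.0, 1.0)


def adaptive_equalize(gray: np.ndarray, params: EnhanceParams = EnhanceParams()) -> np.ndarray:
    """CLAHE over a ``tile_grid x tile_grid`` partition with bilinear blending."""
    gray = _check_gray(gray)
    h, w = gray.shape
    if min(h, w) < params.tile_grid:
        raise ValueError(
            f"image {h}x{w} smaller than tile grid {params.tile_grid}"
        )
    if gray.max() == gray.min():
        return gray.copy()
    kernel = (max(1, h // params.tile_grid), max(1, w // params.tile_grid))
    out = equalize_adapthist(
        np.clip(gray, 0.0, 1.0), kernel_size=kernel, clip_limit=params.clip_limit
    )
    return np.clip(out, 0.0, 1.0)


def top_bottom_hat_enhance(
    gray: np.ndarray, b: StructureElement = StructureElement()
) -> np.ndarray:
    """Enhance structures smaller than ``b`` in both polarities.

    Returns ``clip(gray + tophat - bottomhat)`` where
    ``tophat = gray - opening(gray, b)`` and
    ``bottomhat = closing(gray, b) - gray``.  Microaneurysms (small dark
    dots) become darker relative to the background, exudate specks brighter;
    structures wider than the element in every direction are untouched.
    """
    gray = _check_gray(gray)
    if b.radius >= min(gray.shape) / 2:
        raise ValueError(
            f"structure element radius {b.radius} too large for {gray.shape}"
        )
    fp = b.footprint
    enhanced = gray + white_tophat(gray, fp) - black_tophat(gray, fp)
    return np.clip(enhanced, 0.0, 1.0)


def gray_opening(gray: np.ndarray, b: StructureElement) -> np.ndarray:
    """Grayscale opening (erosion then dilation) by a disk element."""
    return opening(_check_gray(gray), b.footprint)


def gray_closing(gray: np.ndarray, b: StructureElement) -> np.ndarray:
    """Grayscale closing (dilation then erosion) by a disk element."""
    return closing(_check_gray(gray), b.footprint)
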
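"""Microaneurysm detection and counting.

Microaneurysms (MAs) are focal capillary dilations that appear as small dark
red dots of 12-100 um diameter, resolvable in 45-degree fundus photographs
above roughly 30 um.  Two interchangeable protocols are implemented on the
enhanced green channel (CLAHE followed by top/bottom-hat enhancement):

``morphology``
    Otsu threshold -> inverted binarization (dark structures become
    foreground) -> vessel subtraction (structures that survive a 2-px disk
    erosion are reconstructed by dilation and removed) -> size and
    circularity filtering of the remaining dots.

``hough``
    The boundary of the candidate mask votes in a (center_row, center_col,
    radius) accumulator via ``x = a + r cos(theta), y = b + r sin(theta)``;
    a peak is accepted only when its votes approach the number of perimeter
    pixels a circle of that radius would contribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import dilation, erosion, footprint_rectangle
from skimage.morphology import disk as _disk

from .exudates import LabeledRegions, Region, clean_mask, estimate_fov_mask, label_regions
from .fundus_io import PixelCalibration
from .preprocess import EnhanceParams, StructureElement, adaptive_equalize, top_bottom_hat_enhance

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Otsu thresholding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OtsuResult:
    """Outcome of the exhaustive 256-bin Otsu scan.

    ``threshold`` is the cut value in ``(0, 1)``: class C0 holds bins
    ``<= k`` and C1 the rest, with the threshold placed at the upper edge of
    bin ``k``.  ``between_class_variance`` is ``w0*w1*(mu0-mu1)^2`` at the
    chosen cut, maximal over all 256 candidates (lowest cut wins ties) —
    equivalently the cut minimises intra-class variance.
    """

    threshold: float
    class_probs: tuple[float, float]
    class_means: tuple[float, float]
    between_class_variance: float
    histogram: np.ndarray


def otsu_threshold(gray: np.ndarray, mask: np.ndarray | None = None) -> OtsuResult:
    """Exhaustive Otsu scan over 256 gray bins.

    Intensities in ``[0, 1]`` are quantised to bins ``round(g * 255)``; the
    optional ``mask`` restricts the histogram (e.g. to the camera field of
    view).  A constant image has no two classes to separate and raises
    ``ValueError``.
    """
    gray = np.asarray(gray, dtype=np.float64)
    vals = gray[np.asarray(mask, bool)] if mask is not None else gray.ravel()
    if vals.size == 0:
        raise ValueError("no pixels to threshold")
    bins = np.clip(np.round(vals * 255.0), 0, 255).astype(np.intp)
    hist = np.bincount(bins, minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("constant image: Otsu threshold undefined")

    n = hist.sum()
    p = hist / n
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)                      # P(class C0) for cut after bin k
    w1 = 1.0 - w0
    m0 = np.cumsum(p * levels)
    mt = m0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (mt - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=0.0)
    sigma_b[255] = 0.0  # cutting after the last bin leaves one class
    k = int(np.argmax(sigma_b))  # argmax returns the lowest maximiser
    return OtsuResult(
        threshold=(k + 0.5) / 255.0,
        class_probs=(float(w0[k]), float(w1[k])),
        class_means=(float(mu0[k]) / 255.0, float(mu1[k]) / 255.0),
        between_class_variance=float(sigma_b[k]) / 255.0**2,
        histogram=hist.astype(np.int64),
    )


def binarize_invert(gray: np.ndarray, t: float) -> np.ndarray:
    """Dark structures become foreground: ``mask = gray <= t``.

    Vessels and microaneurysms are darker than the retinal background, so
    inverting the binarization makes them the white structures every
    subsequent morphological step operates on.
    """
    if not 0.0 < t < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return np.asarray(gray, dtype=np.float64) <= t


# ---------------------------------------------------------------------------
# Vessel subtraction
# ---------------------------------------------------------------------------

def remove_vessels(
    mask: np.ndarray,
    erode_radius: int = 2,
    dilate_radius: int = 1,
    dilate_difference: bool = False,
) -> np.ndarray:
    """Subtract vessel-calibre structures, keeping sub-element dots.

    Vessels (4-8 px wide) survive erosion by a ``erode_radius``-px disk;
    dilating the survivor by ``erode_radius + dilate_radius`` reconstructs
    their original extent plus a safety margin, and that reconstruction is
    subtracted from the input.  Dots thinner than the erosion element are
    erased by the erosion, so nothing is subtracted where they stand and
    they pass through untouched.  The output is always a subset of the
    input foreground.

    ``dilate_difference=True`` selects the alternative reading in which the
    erosion-difference itself is dilated; it inflates noise and is kept only
    for comparison.
    """
    mask = np.asarray(mask, bool)
    eroded = erosion(mask, _disk(erode_radius))
    if dilate_difference:
        diff = mask & ~dilation(eroded, _disk(erode_radius))
        return mask & dilation(diff, _disk(dilate_radius))
    vessel_estimate = dilation(eroded, _disk(erode_radius + dilate_radius))
    return mask & ~vessel_estimate


def filter_candidates(
    regions: LabeledRegions,
    cal: PixelCalibration,
    d_min_um: float = 30.0,
    d_max_um: float = 100.0,
    min_circularity: float = 0.5,
) -> list[Region]:
    """Keep regions whose equivalent diameter is MA-sized and round enough.

    Equivalent diameter is ``2 * sqrt(area / pi)`` pixels, converted to um
    with the calibration.  The default lower bound is 30 um — the visibility
    limit for MAs in 45-degree fundus photographs — and the upper bound
    100 um, beyond which a red lesion is better read as a hemorrhage.
    """
    kept = []
    for r in regions.regions:
        d_um = 2.0 * np.sqrt(r.area / np.pi) * cal.microns_per_pixel
        if d_min_um <= d_um <= d_max_um and r.circularity >= min_circularity:
            kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# Circular Hough transform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HoughAccumulator:
    """Vote grid over (center_row, center_col, radius index).

    Each edge pixel casts one vote into every distinct accumulator cell on
    its circle of influence: 360 angular samples per radius, deduplicated
    after rounding to the pixel grid, so a perfect rasterized circle drives
    its center cell to approximately the perimeter pixel count.
    """

    votes: np.ndarray  # (n_radii, H, W) int32
    radii: tuple[int, ...]
    edge_count: int
    expected_votes: tuple[int, ...]  # rasterized perimeter count per radius


@dataclass(frozen=True)
class CircleCandidate:
    """A validated circle: center, radius, raw votes and edge support."""

    center: tuple[int, int]
    radius: int
    votes: int
    support: float


def circle_offsets(radius: int, n_angles: int = 360) -> np.ndarray:
    """Distinct integer (dr, dc) offsets on a circle of the given radius."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    theta = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    dr = np.round(radius * np.sin(theta)).astype(np.intp)
    dc = np.round(radius * np.cos(theta)).astype(np.intp)
    return np.unique(np.stack([dr, dc], axis=1), axis=0)


def hough_accumulate(
    edge_mask: np.ndarray, radii: list[int] | tuple[int, ...], n_angles: int = 360
) -> HoughAccumulator:
    """Vote every edge pixel into the (center, radius) parameter space."""
    edge_mask = np.asarray(edge_mask, bool)
    radii = tuple(int(r) for r in radii)
    if len(radii) == 0:
        raise ValueError("radii must be nonempty")
    if any(r < 1 for r in radii):
        raise ValueError("all radii must be >= 1")
    h, w = edge_mask.shape
    edges = np.argwhere(edge_mask)
    votes = np.zeros((len(radii), h, w), dtype=np.int32)
    expected = []
    for i, r in enumerate(radii):
        offs = circle_offsets(r, n_angles)
        expected.append(len(offs))
        if edges.size == 0:
            continue
        centers = edges[:, None, :] - offs[None, :, :]
        centers = centers.reshape(-1, 2)
        ok = (
            (centers[:, 0] >= 0) & (centers[:, 0] < h)
            & (centers[:, 1] >= 0) & (centers[:, 1] < w)
        )
        centers = centers[ok]
        np.add.at(votes[i], (centers[:, 0], centers[:, 1]), 1)
    return HoughAccumulator(
        votes=votes,
        radii=radii,
        edge_count=int(len(edges)),
        expected_votes=tuple(expected),
    )


def hough_circles(
    edge_mask: np.ndarray,
    radii: list[int] | tuple[int, ...],
    support_min: float = 0.5,
    nms_dist: float = 5.0,
    n_angles: int = 360,
) -> list[CircleCandidate]:
    """Detect circles by accumulator peaks validated against perimeter size.

    A cell is a candidate when ``votes / expected_perimeter_pixels(radius)``
    reaches ``support_min``; a complete drawn circle scores support near 1,
    a half circle near 0.5.  Candidates are merged by non-maximum
    suppression: descending support (then votes), suppressing any candidate
    whose center lies within ``nms_dist`` of an accepted one.
    """
    acc = hough_accumulate(edge_mask, radii, n_angles=n_angles)
    cands: list[CircleCandidate] = []
    for i, r in enumerate(acc.radii):
        expected = acc.expected_votes[i]
        plane = acc.votes[i]
        for row, col in np.argwhere(plane >= support_min * expected):
            v = int(plane[row, col])
            cands.append(
                CircleCandidate(
                    center=(int(row), int(col)),
                    radius=r,
                    votes=v,
                    support=v / expected,
                )
            )
    cands.sort(key=lambda c: (-c.support, -c.votes, c.center))
    accepted: list[CircleCandidate] = []
    for c in cands:
        if all(
            (c.center[0] - a.center[0]) ** 2 + (c.center[1] - a.center[1]) ** 2
            > nms_dist**2
            for a in accepted
        ):
            accepted.append(c)
    return accepted


# ---------------------------------------------------------------------------
# End-to-end MA counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MAConfig:
    """Tunables of the MA chain (defaults follow the committed protocol)."""

    b_radius: int = 6            # top/bottom-hat structure element, px
    denoise_sigma: float = 0.8   # Gaussian prefilter between CLAHE and hats
    erode_radius: int = 2        # vessel-subtraction erosion, px
    dilate_radius: int = 1       # extra dilation when reconstructing vessels
    dilate_difference: bool = False
    d_min_um: float = 30.0
    d_max_um: float = 100.0
    min_circularity: float = 0.5
    size_inflation_px: float = 2.0  # segmentation widens dots by ~blur + hat halo
    fov_shrink_px: int = 8       # keep clear of aperture-rim equalization artifacts
    bright_halo_px: int = 0      # also reject dots this close to bright lesions
    min_depth_frac: float = 0.8  # a dot must dip below this fraction of the
                                 # dark threshold (halo artifacts barely cross it)
    support_min: float = 0.5
    nms_dist: float = 5.0
    n_angles: int = 360
    min_area_px: int = 3         # speck removal before candidate analysis
    enhance: EnhanceParams = field(default_factory=EnhanceParams)


@dataclass(frozen=True)
class MAReport:
    """Per-image MA count with the candidates and configuration behind it."""

    count: int
    candidates: tuple
    method: str
    params_used: MAConfig
    threshold_used: float = float("nan")


def ma_candidate_mask(green: np.ndarray, config: MAConfig = MAConfig()) -> tuple[np.ndarray, float]:
    """Shared front end of both protocols: enhanced image -> candidate dots.

    CLAHE, a light Gaussian denoise (the hat transforms are local extreme
    detectors and would otherwise amplify equalized sensor noise into the
    lesion intensity range), then top/bottom-hat enhancement, Otsu within
    the field of view, inverted binarization, and vessel subtraction.
    Two artifact classes are then removed: fragments contiguous with the
    subtracted vessel reconstruction (local pinches where the erosion
    skeleton broke), and shallow dots that never dip below
    ``min_depth_frac`` of the dark threshold — local equalization darkens
    the immediate surround of exudates and the optic disk, leaving round
    dark halo fragments that barely cross the threshold, whereas a genuine
    microaneurysm dips far below it.  ``bright_halo_px`` optionally rejects
    candidates by proximity to bright lesions as well.  Returns the
    candidate mask and the Otsu threshold used.
    """
    from scipy import ndimage as ndi

    green = np.asarray(green, dtype=np.float64)
    fov = estimate_fov_mask(green, shrink=config.fov_shrink_px)
    enhanced = adaptive_equalize(green, config.enhance)
    if config.denoise_sigma > 0:
        enhanced = ndi.gaussian_filter(enhanced, config.denoise_sigma)
    enhanced = top_bottom_hat_enhance(enhanced, StructureElement(radius=config.b_radius))
    t = otsu_threshold(enhanced, mask=fov).threshold
    mask = binarize_invert(enhanced, t) & fov
    vessel_estimate = dilation(
        erosion(mask, _disk(config.erode_radius)),
        _disk(config.erode_radius + config.dilate_radius),
    )
    mask = remove_vessels(
        mask,
        erode_radius=config.erode_radius,
        dilate_radius=config.dilate_radius,
        dilate_difference=config.dilate_difference,
    )
    # drop fragments that border the vessel reconstruction or bright lesions
    reject = dilation(vessel_estimate, _disk(1))
    if config.bright_halo_px > 0:
        from .exudates import segment_exudates

        bright, _ = segment_exudates(enhanced, "otsu", fov_mask=fov)
        reject |= dilation(bright, _disk(config.bright_halo_px))
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if n:
        drop = set(np.unique(labels[reject & (labels > 0)]))
        if config.min_depth_frac > 0:
            # a genuine microaneurysm dips far below the dark threshold;
            # equalization halos barely cross it
            depth_cut = config.min_depth_frac * t
            mins = ndi.minimum(enhanced, labels, index=np.arange(1, n + 1))
            drop.update(np.flatnonzero(mins > depth_cut) + 1)
        if drop:
            mask = mask & ~np.isin(labels, sorted(drop))
    if config.min_area_px > 1:
        mask = clean_mask(mask, open_radius=0, min_area=config.min_area_px)
    return mask, t


def hough_radii_for(cal: PixelCalibration, config: MAConfig = MAConfig()) -> list[int]:
    """Radii (px) to scan for MA-sized rings, padded by 1 px for the
    external boundary used as the Hough edge input."""
    r_min = max(1, int(np.floor(config.d_min_um / (2.0 * cal.microns_per_pixel))))
    r_max = max(r_min, int(np.ceil(config.d_max_um / (2.0 * cal.microns_per_pixel))) + 1)
    return list(range(r_min, r_max + 1))


def count_mas(
    green: np.ndarray,
    cal: PixelCalibration,
    method: str = "morphology",
    config: MAConfig = MAConfig(),
) -> MAReport:
    """Count microaneurysms on a green channel by the chosen protocol."""
    if method not in {"morphology", "hough"}:
        raise ValueError(f"unknown MA method {method!r}")
    mask, t = ma_candidate_mask(green, config)
    if method == "morphology":
        regions = label_regions(mask)
        # the chain widens a dot by roughly the denoise kernel plus the
        # bottom-hat halo, so the upper physical bound gets that allowance
        kept = filter_candidates(
            regions, cal,
            d_min_um=config.d_min_um,
            d_max_um=config.d_max_um
            + config.size_inflation_px * cal.microns_per_pixel,
            min_circularity=config.min_circularity,
        )
        return MAReport(count=len(kept), candidates=tuple(kept), method=method,
                        params_used=config, threshold_used=t)

    # Hough path: external morphological gradient of the candidate mask, so
    # even 1-px dots contribute a votable ring one radius out.
    boundary = dilation(mask, footprint_rectangle((3, 3))) & ~mask
    radii = hough_radii_for(cal, config)
    circles = hough_circles(
        boundary, radii,
        support_min=config.support_min,
        nms_dist=config.nms_dist,
        n_angles=config.n_angles,
    )
    return MAReport(count=len(circles), candidates=tuple(circles), method=method,
                    params_used=config, threshold_used=t)
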
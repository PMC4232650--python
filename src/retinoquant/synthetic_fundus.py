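"""Seeded generator of fundus-like phantoms with exact ground truth.

A phantom emulates a 45-degree field-of-view colour fundus photograph at the
standard 685 x 584 working size: a circular aperture with dark corners, a
radially vignetted background, a bright optic disk, dark vessels random-
walking out of the disk, bright irregular exudate blobs, and small dark
circular microaneurysms.  The green channel carries the strongest lesion
contrast, mirroring why real fundus analysis starts from it.  Ground-truth
masks are the ideal pre-noise shapes, so detector output can be scored
exactly.

Default calibration is 25 um/px — the scale of a 45-degree FOV standardized
to 685 x 584 (the aperture spans ~13.5 mm of retina over ~540 px).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import line as draw_line
from skimage.morphology import dilation
from skimage.morphology import disk as _disk

from .fundus_io import FundusImage, PixelCalibration, write_image, write_mask


class PlacementError(RuntimeError):
    """Could not place all requested lesions without overlap."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic fundus image.

    Lesion geometry is expressed in pixels except MA diameters, which are in
    microns and converted through ``microns_per_pixel`` exactly as the
    detectors convert back.  All lesions are placed inside the circular
    aperture, pairwise disjoint and clear of the optic disk.
    """

    width: int = 685
    height: int = 584
    microns_per_pixel: float = 25.0
    # optic disk: slightly nasal of center, as in a macula-centred photograph
    disk_center: tuple[float, float] | None = None
    disk_radius_px: float = 30.0
    disk_brightness: float = 0.35
    n_vessels: int = 7
    vessel_width_px: tuple[int, int] = (4, 8)
    vessel_depth: float = 0.20
    n_exudates: int = 6
    exudate_area_px: tuple[float, float] = (400.0, 1200.0)
    exudate_brightness: tuple[float, float] = (0.15, 0.30)
    n_mas: int = 14
    ma_diameter_um: tuple[float, float] = (30.0, 80.0)
    ma_depth: float = 0.30
    background: float = 0.45
    vignette: float = 0.15
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_vessels, self.n_exudates, self.n_mas) < 0:
            raise ValueError("lesion counts must be >= 0")
        lo, hi = self.ma_diameter_um
        if not (12.0 <= lo <= hi <= 100.0):
            raise ValueError("ma_diameter_um must lie within [12, 100] um")
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be > 0")

    @property
    def calibration(self) -> PixelCalibration:
        return PixelCalibration(microns_per_pixel=self.microns_per_pixel)


@dataclass(frozen=True)
class GroundTruth:
    """Exact planted shapes and totals for recovery scoring."""

    exudate_mask: np.ndarray
    disk_mask: np.ndarray
    vessel_mask: np.ndarray
    ma_mask: np.ndarray
    ma_centers: tuple[tuple[float, float, float], ...]  # (row, col, radius_px)
    exudate_area: int
    disk_area: int
    true_ratio: float
    ma_count: int


def _fov_geometry(spec: PhantomSpec) -> tuple[float, float, float]:
    return spec.height / 2.0, spec.width / 2.0, min(spec.height, spec.width) / 2.0 - 6.0


def _dist_grid(h: int, w: int, cr: float, cc: float) -> np.ndarray:
    yy, xx = np.mgrid[:h, :w]
    return np.hypot(yy - cr, xx - cc)


def make_phantom(spec: PhantomSpec) -> tuple[FundusImage, GroundTruth]:
    """Render one phantom deterministically from its spec (and seed)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    fov_cr, fov_cc, fov_r = _fov_geometry(spec)
    dist_fov = _dist_grid(h, w, fov_cr, fov_cc)
    fov = dist_fov <= fov_r

    # background with radial vignette
    green = np.where(
        fov, spec.background * (1.0 - spec.vignette * (dist_fov / fov_r) ** 2), 0.03
    )

    # optic disk
    if spec.disk_center is None:
        disk_cr, disk_cc = fov_cr, fov_cc + 0.45 * fov_r
    else:
        disk_cr, disk_cc = spec.disk_center
    ddisk = _dist_grid(h, w, disk_cr, disk_cc)
    disk_cov = np.clip(spec.disk_radius_px + 0.5 - ddisk, 0.0, 1.0)
    disk_mask = ddisk <= spec.disk_radius_px
    if not disk_mask.any() or not fov[disk_mask].all():
        raise PlacementError("optic disk does not fit inside the aperture")
    green = green + spec.disk_brightness * disk_cov

    vessel_mask = _render_vessels(spec, rng, fov, (disk_cr, disk_cc), fov_r)
    green = green - spec.vessel_depth * ndi.gaussian_filter(
        vessel_mask.astype(np.float64), 0.7
    )

    keepout = disk_mask | vessel_mask
    exudate_mask, exu_delta = _render_exudates(spec, rng, fov, keepout)
    green = green + exu_delta

    keepout = keepout | exudate_mask
    ma_mask, ma_centers, ma_delta = _render_mas(spec, rng, fov, keepout)
    green = green - ma_delta

    lesion_delta = (
        spec.disk_brightness * disk_cov
        + exu_delta
        - spec.vessel_depth * vessel_mask
        - ma_delta
    )
    red = np.where(fov, 0.58 * (1.0 - 0.5 * spec.vignette * (dist_fov / fov_r) ** 2), 0.04)
    red = red + 0.55 * lesion_delta
    blue = np.where(fov, 0.12, 0.02) + 0.25 * lesion_delta

    channels = []
    for plane in (red, green, blue):
        noisy = plane + rng.normal(0.0, spec.noise_sd, size=plane.shape)
        channels.append(np.clip(noisy, 0.0, 1.0))
    pixels = np.clip(np.round(np.stack(channels, axis=-1) * 255.0), 0, 255).astype(np.uint8)

    exu_area = int(exudate_mask.sum())
    disk_area = int(disk_mask.sum())
    truth = GroundTruth(
        exudate_mask=exudate_mask,
        disk_mask=disk_mask,
        vessel_mask=vessel_mask,
        ma_mask=ma_mask,
        ma_centers=tuple(ma_centers),
        exudate_area=exu_area,
        disk_area=disk_area,
        true_ratio=exu_area / disk_area,
        ma_count=len(ma_centers),
    )
    return FundusImage(pixels=pixels, source_path=""), truth


def _render_vessels(spec, rng, fov, start, fov_r):
    """Random walks leaving the disk rim, drawn as thick polylines."""
    h, w = fov.shape
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_vessels):
        width = int(rng.integers(spec.vessel_width_px[0], spec.vessel_width_px[1] + 1))
        theta = rng.uniform(0.0, 2.0 * np.pi)
        r0, c0 = (
            start[0] + (spec.disk_radius_px + 1) * np.sin(theta),
            start[1] + (spec.disk_radius_px + 1) * np.cos(theta),
        )
        path = np.zeros((h, w), dtype=bool)
        steps = int(1.2 * fov_r / 6)
        for _ in range(steps):
            theta += rng.normal(0.0, 0.35)
            r1, c1 = r0 + 6.0 * np.sin(theta), c0 + 6.0 * np.cos(theta)
            rr0, cc0 = int(round(r0)), int(round(c0))
            rr1, cc1 = int(round(r1)), int(round(c1))
            if not (0 <= rr1 < h and 0 <= cc1 < w) or not fov[rr1, cc1]:
                break
            rr, cc = draw_line(rr0, cc0, rr1, cc1)
            path[rr, cc] = True
            r0, c0 = r1, c1
        mask |= dilation(path, _disk(max(1, width // 2)))
    return mask & fov


def _place(rng, fov, keepout, stamp_radius, margin, max_tries=500):
    """Rejection-sample a center whose stamp neighbourhood is free."""
    h, w = fov.shape
    pad = int(np.ceil(stamp_radius + margin))
    for _ in range(max_tries):
        r = float(rng.uniform(pad, h - pad))
        c = float(rng.uniform(pad, w - pad))
        rr, cc = int(round(r)), int(round(c))
        lo_r, hi_r = rr - pad, rr + pad + 1
        lo_c, hi_c = cc - pad, cc + pad + 1
        if not fov[lo_r:hi_r, lo_c:hi_c].all():
            continue
        if keepout[lo_r:hi_r, lo_c:hi_c].any():
            continue
        return r, c
    raise PlacementError("could not place lesion after bounded retries")


def _render_exudates(spec, rng, fov, keepout, max_tries=300):
    """Bright irregular blobs: unions of jittered disks around a center.

    Candidate blobs are built in a local patch and accepted only when their
    actual support lies inside the aperture and clear of everything already
    placed (blobs may sit near each other, as real exudates do)."""
    h, w = fov.shape
    mask = np.zeros((h, w), dtype=bool)
    delta = np.zeros((h, w), dtype=np.float64)
    occupied = keepout.copy()
    for _ in range(spec.n_exudates):
        area = rng.uniform(*spec.exudate_area_px)
        r0 = float(np.sqrt(area / np.pi))
        pad = int(np.ceil(1.6 * r0)) + 2
        for _try in range(max_tries):
            cr = float(rng.uniform(pad, h - pad - 1))
            cc = float(rng.uniform(pad, w - pad - 1))
            rr, cc_i = int(round(cr)), int(round(cc))
            lo_r, lo_c = rr - pad, cc_i - pad
            side = 2 * pad + 1
            yy, xx = np.mgrid[:side, :side]
            blob_local = np.zeros((side, side), dtype=bool)
            for _ in range(5):
                sub_r = rng.uniform(0.55, 0.8) * r0
                ang = rng.uniform(0.0, 2.0 * np.pi)
                rad = rng.uniform(0.0, 0.6) * r0
                scr = (cr - lo_r) + rad * np.sin(ang)
                scc = (cc - lo_c) + rad * np.cos(ang)
                blob_local |= np.hypot(yy - scr, xx - scc) <= sub_r
            fov_local = fov[lo_r:lo_r + side, lo_c:lo_c + side]
            occ_local = occupied[lo_r:lo_r + side, lo_c:lo_c + side]
            if (blob_local & ~fov_local).any() or (blob_local & occ_local).any():
                continue
            blob = np.zeros((h, w), dtype=bool)
            blob[lo_r:lo_r + side, lo_c:lo_c + side] = blob_local
            brightness = rng.uniform(*spec.exudate_brightness)
            delta += brightness * ndi.gaussian_filter(blob.astype(np.float64), 0.8)
            mask |= blob
            occupied |= dilation(blob, _disk(3))
            break
        else:
            raise PlacementError("could not place lesion after bounded retries")
    return mask, delta


def _render_mas(spec, rng, fov, keepout):
    """Small dark anti-aliased dots, pairwise well separated."""
    h, w = fov.shape
    mask = np.zeros((h, w), dtype=bool)
    delta = np.zeros((h, w), dtype=np.float64)
    occupied = keepout.copy()
    centers: list[tuple[float, float, float]] = []
    for _ in range(spec.n_mas):
        d_um = rng.uniform(*spec.ma_diameter_um)
        r_px = d_um / (2.0 * spec.microns_per_pixel)
        cr, cc = _place(rng, fov, occupied, r_px, margin=10)
        d = _dist_grid(h, w, cr, cc)
        cov = np.clip(r_px + 0.5 - d, 0.0, 1.0)
        delta += spec.ma_depth * cov
        dot = cov >= 0.5
        mask |= dot
        occupied |= d <= r_px + 10
        centers.append((cr, cc, r_px))
    return mask, centers, delta


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def make_cohort(
    moderate_spec: PhantomSpec,
    severe_spec: PhantomSpec,
    n_per_group: int,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[tuple[FundusImage, GroundTruth]]]:
    """Generate a two-group phantom cohort with per-image jitter.

    Lesion counts are jittered Poisson around each group template (blob
    areas and MA diameters are already sampled uniformly per lesion inside
    :func:`make_phantom`).  Returns the manifest (image_id, group,
    true_ratio, true_ma_count, path) and the rendered images; when
    ``out_dir`` is given, images, ground-truth masks/JSON and the manifest
    CSV are also written there.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    rendered: list[tuple[FundusImage, GroundTruth]] = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "truth").mkdir(parents=True, exist_ok=True)
    for group, template in (("moderate", moderate_spec), ("severe", severe_spec)):
        for i in range(n_per_group):
            child_seed = int(rng.integers(0, 2**31 - 1))
            n_exu = int(rng.poisson(template.n_exudates))
            n_mas = int(rng.poisson(template.n_mas))
            spec = dataclasses.replace(
                template, n_exudates=n_exu, n_mas=n_mas, seed=child_seed
            )
            img, truth = make_phantom(spec)
            image_id = f"{group}_{i:03d}"
            path = ""
            if out_dir is not None:
                path = str(out_dir / "images" / f"{image_id}.png")
                write_image(img, path)
                write_mask(truth.exudate_mask, out_dir / "truth" / f"{image_id}_exudates.png")
                write_mask(truth.disk_mask, out_dir / "truth" / f"{image_id}_disk.png")
                write_mask(truth.vessel_mask, out_dir / "truth" / f"{image_id}_vessels.png")
                with open(out_dir / "truth" / f"{image_id}.json", "w") as fh:
                    json.dump(
                        {
                            "ma_centers": [list(c) for c in truth.ma_centers],
                            "exudate_area": truth.exudate_area,
                            "disk_area": truth.disk_area,
                            "true_ratio": truth.true_ratio,
                            "ma_count": truth.ma_count,
                            "seed": spec.seed,
                        },
                        fh,
                        indent=2,
                    )
            rows.append(
                {
                    "image_id": image_id,
                    "group": group,
                    "true_ratio": truth.true_ratio,
                    "true_ma_count": truth.ma_count,
                    "path": path,
                }
            )
            rendered.append((img, truth))
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest, rendered
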
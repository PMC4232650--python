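"""Glue for running the full per-image pipeline and whole cohorts."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exudates import ExudateReport, measure_exudates
from .fundus_io import (
    STANDARD_HEIGHT,
    STANDARD_WIDTH,
    FundusImage,
    PixelCalibration,
    extract_green,
    read_image,
    standardize,
)
from .microaneurysms import MAConfig, MAReport, count_mas
from .preprocess import EnhanceParams
from .stats_report import GroupComparison, compare_groups

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything tunable in one place, validated by the modules it feeds."""

    microns_per_pixel: float = 25.0
    enhance: EnhanceParams = field(default_factory=EnhanceParams)
    ma: MAConfig = field(default_factory=MAConfig)
    exudate_threshold: float | str = "otsu"
    exudate_open_radius: int = 1
    exudate_min_area: int = 5
    disk_radius_range: tuple[float, float] = (15.0, 60.0)
    ma_method: str = "morphology"
    standardize_inputs: bool = True

    @property
    def calibration(self) -> PixelCalibration:
        return PixelCalibration(microns_per_pixel=self.microns_per_pixel)


def prepare_image(img: FundusImage, config: RunConfig) -> tuple[FundusImage, PixelCalibration]:
    """Standardise to 685 x 584 and rescale the calibration to match."""
    cal = config.calibration
    if config.standardize_inputs and (img.width, img.height) != (
        STANDARD_WIDTH, STANDARD_HEIGHT
    ):
        original_width = img.width
        img = standardize(img)
        cal = cal.rescaled(original_width, STANDARD_WIDTH)
    return img, cal


def analyze_image(
    img: FundusImage | str | Path,
    config: RunConfig = RunConfig(),
    manual_disk_mask: np.ndarray | None = None,
) -> tuple[ExudateReport, MAReport]:
    """Run both detectors on one image (path or in-memory)."""
    if not isinstance(img, FundusImage):
        img = read_image(img)
    img, cal = prepare_image(img, config)
    exu = measure_exudates(
        img,
        enhance=config.enhance,
        threshold=config.exudate_threshold,
        manual_disk_mask=manual_disk_mask,
        open_radius=config.exudate_open_radius,
        min_area=config.exudate_min_area,
        disk_radius_range=config.disk_radius_range,
    )
    ma = count_mas(extract_green(img), cal, method=config.ma_method, config=config.ma)
    return exu, ma


def run_cohort(
    manifest: pd.DataFrame,
    config: RunConfig = RunConfig(),
    images: list[FundusImage] | None = None,
) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Measure every image in a cohort manifest and compare the two groups.

    ``manifest`` needs columns image_id, group and either path or an
    ``images`` list aligned with its rows.  Per-image failures are logged
    and skipped; if every image fails, a RuntimeError is raised.
    """
    if "group" not in manifest.columns or "image_id" not in manifest.columns:
        raise ValueError("manifest needs image_id and group columns")
    if manifest["group"].nunique() != 2:
        raise ValueError("cohort comparison needs exactly 2 groups")
    rows = []
    for i, rec in enumerate(manifest.itertuples(index=False)):
        source = images[i] if images is not None else rec.path
        try:
            exu, ma = analyze_image(source, config)
        except Exception:  # noqa: BLE001 - per-image isolation
            logger.exception("failed to analyze %s; skipping", rec.image_id)
            continue
        rows.append(
            {
                "image_id": rec.image_id,
                "group": rec.group,
                "exudates_disk_ratio": exu.exudates_disk_ratio,
                "n_exudate_lesions": exu.n_lesions,
                "total_exudate_area_px": exu.total_exudate_area,
                "disk_area_px": exu.disk_area,
                "disk_source": exu.disk_source,
                "ma_count": ma.count,
                "ma_method": ma.method,
            }
        )
    if not rows:
        raise RuntimeError("every image in the cohort failed to process")
    table = pd.DataFrame(rows)
    comparisons = [
        compare_groups(table, "exudates_disk_ratio"),
        compare_groups(table, "ma_count"),
    ]
    return table, comparisons
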
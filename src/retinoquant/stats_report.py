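"""Cohort aggregation and two-sample comparison.

Per-image measurements (exudates/disk ratio, MA count) are summarised per
group as mean +/- sample SD and compared with a two-sided two-sample t-test:
pooled-variance Student's t by default, Welch's t as an option since equal
group variances are rarely verifiable.  P < 0.05 is flagged significant.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    groups: tuple[str, str]
    n: tuple[int, int]
    mean: tuple[float, float]
    sd: tuple[float, float]
    t_statistic: float
    df: float
    p_value: float
    significant: bool
    variant: str


def _check_table(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    for col in ("group", metric):
        if col not in table.columns:
            raise ValueError(f"cohort table lacks column {col!r}")
    return table


def summarize(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-group n, mean and sample SD (n-1 denominator) of one metric."""
    table = _check_table(table, metric)
    out = (
        table.groupby("group", sort=True)[metric]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    if (out["n"] < 2).any():
        raise ValueError("every group needs at least 2 observations")
    return out


def compare_groups(
    table: pd.DataFrame, metric: str, variant: str = "student"
) -> GroupComparison:
    """Two-sided two-sample t-test between exactly two groups.

    ``variant="student"`` pools the variances (df = n1 + n2 - 2);
    ``variant="welch"`` uses Welch-Satterthwaite degrees of freedom.
    """
    if variant not in {"student", "welch"}:
        raise ValueError(f"unknown t-test variant {variant!r}")
    table = _check_table(table, metric)
    names = sorted(table["group"].unique())
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {names}")
    a = table.loc[table["group"] == names[0], metric].to_numpy(float)
    b = table.loc[table["group"] == names[1], metric].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("every group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return GroupComparison(
        metric=metric,
        groups=(names[0], names[1]),
        n=(len(a), len(b)),
        mean=(float(a.mean()), float(b.mean())),
        sd=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < ALPHA),
        variant=variant,
    )


def compare_from_stats(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float,
    variant: str = "student",
) -> GroupComparison:
    """Two-sample t-test reconstructed from printed summary statistics."""
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "student")
    )
    df = (n1 + n2 - 2) if variant == "student" else _welch_df(sd1, n1, sd2, n2)
    return GroupComparison(
        metric="summary",
        groups=("group1", "group2"),
        n=(n1, n2),
        mean=(mean1, mean2),
        sd=(sd1, sd2),
        t_statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < ALPHA),
        variant=variant,
    )


def _welch_df(sd1: float, n1: int, sd2: float, n2: int) -> float:
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    return (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))


def write_report(
    table: pd.DataFrame,
    comparisons: list[GroupComparison],
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write measurements.csv and summary.json; deterministic for fixed input."""
    if len(table) == 0:
        raise ValueError("empty measurement table")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "measurements.csv"
    table.to_csv(csv_path, index=False)
    summary: dict = {"n_images": int(len(table)), "comparisons": []}
    for comp in comparisons:
        d = asdict(comp)
        summary["comparisons"].append(d)
        summary.setdefault("group_summaries", {})[comp.metric] = {
            g: {"n": n, "mean": m, "sd": s}
            for g, n, m, s in zip(comp.groups, comp.n, comp.mean, comp.sd)
        }
    json_path = out_dir / "summary.json"
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return csv_path, json_path
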
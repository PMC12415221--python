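"""Presynaptic-connectivity tabulation from monosynaptic rabies tracing.

A count table has one row per (starter neuron, cortical region, hemisphere)
with the number of retrogradely labelled presynaptic neurons.  Regions are
a fixed controlled vocabulary (secondary/primary motor, somatosensory,
frontal association, orbital, insular, ectorhinal cortex, plus "other");
region assignment is an input, not a computation.  Summaries are offset
geometric means (counts are right-skewed); group comparisons run on
log10(count + 0.5)-transformed per-starter totals.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats
from .synth import REGIONS

__all__ = [
    "REGIONS",
    "HEMISPHERES",
    "COUNT_COLUMNS",
    "validate_count_table",
    "total_per_starter",
    "regional_profile",
    "compare_groups",
]

HEMISPHERES = ("ipsi", "contra")
COUNT_COLUMNS = ("starter_id", "group", "region", "hemisphere", "count")


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and invariants of a presynaptic count table.

    Checks columns, the region/hemisphere vocabularies, nonnegative integer
    counts, and uniqueness of (starter_id, region, hemisphere).  Returns the
    table unchanged on success.
    """
    missing = set(COUNT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"count table missing column(s) {sorted(missing)}")
    bad_region = set(table["region"].unique()) - set(REGIONS)
    if bad_region:
        raise ValueError(f"unknown region code(s) {sorted(bad_region)}; expected {REGIONS}")
    bad_hemi = set(table["hemisphere"].unique()) - set(HEMISPHERES)
    if bad_hemi:
        raise ValueError(f"unknown hemisphere label(s) {sorted(bad_hemi)}")
    counts = table["count"].to_numpy()
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be integers")
    dup = table.duplicated(subset=["starter_id", "region", "hemisphere"])
    if dup.any():
        keys = table.loc[dup, ["starter_id", "region", "hemisphere"]].values.tolist()
        raise ValueError(f"duplicate (starter, region, hemisphere) rows: {keys[:5]}")
    return table


def total_per_starter(table: pd.DataFrame) -> pd.DataFrame:
    """Total presynaptic neurons per starter (summed over regions and hemispheres)."""
    validate_count_table(table)
    out = (
        table.groupby(["starter_id", "group"], observed=True, sort=True)["count"]
        .sum()
        .reset_index()
        .rename(columns={"count": "total"})
    )
    return out


def regional_profile(table: pd.DataFrame) -> pd.DataFrame:
    """Offset geometric-mean counts per (region, hemisphere, group).

    Cells with no observations are simply absent from the output (the assay
    counts only labelled sections, so a missing cell is structurally
    missing, not zero).
    """
    validate_count_table(table)
    frames = []
    for (region, hemi), sub in table.groupby(["region", "hemisphere"], observed=True, sort=True):
        summ = stats.geometric_mean_summary(sub, value="count", group="group")
        summ.insert(0, "hemisphere", hemi)
        summ.insert(0, "region", region)
        frames.append(summ)
    return pd.concat(frames, ignore_index=True)


def compare_groups(totals: pd.DataFrame, correction: str | None = None) -> stats.AnovaResult:
    """ANOVA + pairwise contrasts on log10(total + 0.5) per-starter totals.

    `totals` is the output of :func:`total_per_starter`.  Returns the
    :class:`~silencescope.stats.AnovaResult` with the pairwise contrast
    table attached.
    """
    if "total" not in totals.columns or "group" not in totals.columns:
        raise ValueError("totals table needs columns 'total' and 'group'")
    work = totals.copy()
    work["log_total"] = stats.log_count_transform(work["total"].to_numpy())
    fit = stats.anova_oneway(work, value="log_total", group="group")
    fit.pairwise = stats.posthoc_pairwise(
        work, fit, value="log_total", group="group", correction=correction
    )
    return fit
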
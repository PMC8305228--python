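"""Per-taxon summaries of ¹³C incorporation and microcosm rate arithmetic.

Aggregates peptide-level RIA and generation-time estimates into per-genus,
per-condition, per-timepoint boxplot statistics (Tukey convention, as drawn
in labeling-pattern figures), assigns each taxon an activity class by
majority vote over its peptides, and computes substrate consumption rates
and their fold-changes between incubation windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import classify_activity, majority_call

__all__ = [
    "RateSeries",
    "FoldChange",
    "summarize_taxa",
    "consumption_rate",
    "fold_change",
]


@dataclass(frozen=True)
class RateSeries:
    """Concentration-time series for one analyte (e.g. O2 in µM, Fe(II) in mM)."""

    analyte: str
    times: tuple[float, ...]  # days, strictly increasing
    concentrations: tuple[float, ...]
    units: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        c = np.asarray(self.concentrations, float)
        if t.size != c.size:
            raise ValueError("times and concentrations must have equal length")
        if t.size and (np.diff(t) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (c < 0).any():
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class FoldChange:
    """Ratio of a late to an early rate, with print-style rounding.

    ``rounded`` follows reporting convention: integer folds at or above 10,
    one decimal below.  ``raw`` always retains the unrounded ratio.
    """

    raw: float
    rounded: float

    def __str__(self) -> str:
        if self.rounded == int(self.rounded):
            return f"{int(self.rounded)}-fold"
        return f"{self.rounded}-fold"


def _tukey_stats(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = np.sort(values[(values < lo_fence) | (values > hi_fence)])
    return {
        "q1": q1,
        "median": med,
        "q3": q3,
        "whisker_low": inside.min() if inside.size else np.nan,
        "whisker_high": inside.max() if inside.size else np.nan,
        "outliers": ";".join(f"{v:g}" for v in outliers),
    }


def summarize_taxa(
    per_peptide: pd.DataFrame,
    autotroph_threshold: float = 90.0,
    inactive_tol: float = 0.5,
) -> pd.DataFrame:
    """Boxplot-style RIA summaries per (genus, condition, timepoint).

    Requires columns ``genus``, ``condition``, ``timepoint``, ``ria_percent``;
    uses ``td`` (generation time) when present.  Replicates are pooled.
    Whiskers/outliers follow the Tukey 1.5·IQR convention; groups without
    any peptide are simply not emitted.  The taxon activity call is the
    majority vote of per-peptide calls, ties broken toward the less labeled
    class.
    """
    required = {"genus", "condition", "timepoint", "ria_percent"}
    missing = required - set(per_peptide.columns)
    if missing:
        raise ValueError(f"per-peptide table missing columns: {sorted(missing)}")
    rows = []
    grouped = per_peptide.groupby(["genus", "condition", "timepoint"], sort=True)
    for (genus, condition, timepoint), grp in grouped:
        ria = grp["ria_percent"].to_numpy(float)
        ria = ria[~np.isnan(ria)]
        if ria.size == 0:
            continue
        stats = _tukey_stats(ria)
        labels = [
            classify_activity(v, autotroph_threshold, inactive_tol).label for v in ria
        ]
        row = {
            "genus": genus,
            "condition": condition,
            "timepoint": timepoint,
            "n_peptides": int(ria.size),
            "ria_q1": stats["q1"],
            "ria_median": stats["median"],
            "ria_q3": stats["q3"],
            "ria_whisker_low": stats["whisker_low"],
            "ria_whisker_high": stats["whisker_high"],
            "ria_outliers": stats["outliers"],
            "activity": majority_call(labels),
        }
        if "td" in grp.columns:
            td = grp["td"].to_numpy(float)
            td = td[np.isfinite(td)]
            row["td_median"] = float(np.median(td)) if td.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def consumption_rate(series: RateSeries, window: tuple[float, float] | None = None) -> float:
    """Consumption rate over a time window: minus the least-squares slope
    of concentration versus time (concentration units per day)."""
    t = np.asarray(series.times, float)
    c = np.asarray(series.concentrations, float)
    if window is not None:
        lo, hi = window
        mask = (t >= lo) & (t <= hi)
        t, c = t[mask], c[mask]
    if t.size < 2:
        raise ValueError("need at least 2 points in the window to fit a rate")
    slope = np.polyfit(t, c, 1)[0]
    return float(-slope)


def fold_change(rate_early: float, rate_late: float) -> FoldChange:
    """Fold increase of a late rate over an early rate.

    Rounded to integer folds at/above 10, one decimal below — mirroring how
    such rate increases are conventionally printed.  The raw ratio is kept.
    """
    if rate_early == 0:
        raise ValueError("fold change undefined: early rate is zero")
    raw = rate_late / rate_early
    rounded = float(round(raw)) if raw >= 10 else round(raw, 1)
    return FoldChange(raw=raw, rounded=rounded)
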
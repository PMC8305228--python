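"""Doublings, generation times, and trophic activity classification.

From the unlabeled/labeled signal intensities of a peptide, the number of
population doublings over the incubation is

    n = log2((I12C + I13C) / I12C)

and the generation time is td = Δt / n, where Δt is the incubation span.
The peptide's RIA separates trophic lifestyles: values above 90 % indicate
autotrophs assimilating the ¹³CO₂ tracer directly, values between natural
abundance (1.1 %) and 90 % indicate heterotrophs labeled by cross-feeding,
and values at natural abundance indicate inactive organisms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ActivityCall",
    "GrowthEstimate",
    "doublings",
    "generation_time",
    "classify_activity",
    "growth_table",
    "AUTOTROPH",
    "CROSSFED",
    "INACTIVE",
]

AUTOTROPH = "autotroph"
CROSSFED = "crossfed_heterotroph"
INACTIVE = "inactive"

#: Ranking used for conservative tie-breaks: lower = less labeled.
CLASS_ORDER = {INACTIVE: 0, CROSSFED: 1, AUTOTROPH: 2}

NATURAL_RIA_PERCENT = 1.1


@dataclass(frozen=True)
class GrowthEstimate:
    """Doublings and generation time for one peptide over one incubation."""

    n: float
    td: float  # days; NaN when undefined (no growth or complete turnover)
    delta_t: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ActivityCall:
    """Trophic class assigned from a peptide or taxon RIA (percent)."""

    label: str
    ria: float
    autotroph_threshold: float
    inactive_tol: float
    flags: tuple[str, ...] = ()


def doublings(i12c: float, i13c: float) -> float:
    """Number of doublings n = log2((I12C + I13C) / I12C).

    Returns NaN for I12C = 0 (complete turnover — the unlabeled pool is
    exhausted and n is undefined rather than infinite).
    """
    if i12c < 0 or i13c < 0:
        raise ValueError("signal intensities must be non-negative")
    if i12c == 0:
        return float("nan")
    return math.log2((i12c + i13c) / i12c)


def generation_time(n: float, delta_t: float) -> float:
    """Generation time td = Δt / n (days); NaN when n = 0 (no growth)."""
    if not delta_t > 0:
        raise ValueError("incubation time delta_t must be positive")
    if math.isnan(n):
        return float("nan")
    if n < 0:
        raise ValueError("doublings n cannot be negative")
    if n == 0:
        return float("nan")
    return delta_t / n


def classify_activity(
    ria: float,
    autotroph_threshold: float = 90.0,
    inactive_tol: float = 0.5,
) -> ActivityCall:
    """Assign a trophic class from an RIA in percent.

    * ria > ``autotroph_threshold`` (strict) → autotroph
    * within ``inactive_tol`` points of natural abundance (1.1 %) → inactive
    * in between → cross-fed heterotroph

    RIA below natural abundance minus the tolerance is a measurement
    anomaly: classified inactive but flagged ``sub-natural``.
    """
    if not 0.0 <= ria <= 100.0:
        raise ValueError("ria must be a percentage in [0, 100]")
    flags: tuple[str, ...] = ()
    if ria > autotroph_threshold:
        label = AUTOTROPH
    elif ria >= NATURAL_RIA_PERCENT - inactive_tol:
        if abs(ria - NATURAL_RIA_PERCENT) <= inactive_tol:
            label = INACTIVE
        else:
            label = CROSSFED
    else:
        label = INACTIVE
        flags = ("sub-natural",)
    return ActivityCall(label, ria, autotroph_threshold, inactive_tol, flags)


def majority_call(labels) -> str:
    """Majority vote over per-peptide class labels; ties go to the less
    labeled class (conservative)."""
    counts = pd.Series(list(labels)).value_counts()
    top = counts[counts == counts.max()].index
    return min(top, key=lambda lbl: CLASS_ORDER[lbl])


def growth_table(
    ria_table: pd.DataFrame,
    autotroph_threshold: float = 90.0,
    inactive_tol: float = 0.5,
) -> pd.DataFrame:
    """Per-peptide growth estimates and activity calls from an RIA table.

    Expects columns ``I12C``, ``I13C``, ``timepoint`` (the incubation span
    Δt in days) and ``ria_percent``.  Adds ``n``, ``td``, ``activity`` and
    ``growth_flags``.
    """
    for col in ("I12C", "I13C", "timepoint", "ria_percent"):
        if col not in ria_table.columns:
            raise ValueError(f"ria table is missing required column {col!r}")
    out = ria_table.copy()
    ns, tds, labels, flag_col = [], [], [], []
    for _, row in out.iterrows():
        flags = []
        n = doublings(float(row["I12C"]), float(row["I13C"]))
        if math.isnan(n):
            flags.append("complete-turnover")
            td = float("nan")
        else:
            td = generation_time(n, float(row["timepoint"]))
            if math.isnan(td):
                flags.append("no-growth")
        ria = float(row["ria_percent"])
        if math.isnan(ria):
            labels.append("")
            flags.append("ria-undetermined")
        else:
            call = classify_activity(ria, autotroph_threshold, inactive_tol)
            labels.append(call.label)
            flags.extend(call.flags)
        ns.append(n)
        tds.append(td)
        flag_col.append(";".join(flags))
    out["n"] = ns
    out["td"] = tds
    out["activity"] = labels
    out["growth_flags"] = flag_col
    return out
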
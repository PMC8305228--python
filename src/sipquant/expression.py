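"""Expressed-gene calling and pathway coverage from gene count matrices.

Counts are normalized to log2 counts-per-million (log2CPM).  Pooled
log2CPM values of metatranscriptome count tables are typically bimodal: a
low mode of unexpressed/background genes and a main expression mode.  The
expression cutoff is placed at the density valley between these modes
(kernel density estimate, Silverman bandwidth); a gene is called expressed
when it exceeds the cutoff in at least ``min_samples`` samples.  Pathway
coverage is the expressed fraction of each pathway's genes within one
genome, rendered complete / incomplete / absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

__all__ = [
    "CutoffResult",
    "ExpressionCallSet",
    "log2cpm",
    "determine_cutoff",
    "expressed_genes",
    "pathway_coverage",
    "COMPLETE",
    "INCOMPLETE",
    "ABSENT",
]

COMPLETE = "complete"
INCOMPLETE = "incomplete"
ABSENT = "absent"


@dataclass(frozen=True)
class CutoffResult:
    """An expression cutoff in log2CPM units and how it was obtained."""

    cutoff: float
    method: str  # "valley" | "percentile-fallback" | "manual"


@dataclass(frozen=True)
class ExpressionCallSet:
    """Per-gene expressed flags plus the rule that produced them."""

    expressed: pd.Series  # bool, indexed by gene
    cutoff: float
    min_samples: int

    @property
    def expressed_set(self) -> set:
        return set(self.expressed.index[self.expressed])


def log2cpm(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million: log2((count + pc) / (libsize + 2·pc) · 1e6).

    ``counts`` is genes × samples with non-negative entries; library size is
    the column sum.  The pseudo-count keeps zero counts finite (pc = 0
    reproduces the plain definition but maps zeros to −inf).
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("count matrix contains negative entries")
    libsize = arr.sum(axis=0)
    zero = np.flatnonzero(libsize <= 0)
    if zero.size:
        names = [str(counts.columns[i]) for i in zero]
        raise ValueError(f"zero library size in sample(s): {', '.join(names)}")
    with np.errstate(divide="ignore"):
        vals = np.log2((arr + pseudocount) / (libsize + 2.0 * pseudocount) * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def determine_cutoff(
    values,
    manual: float | None = None,
    bw_method="silverman",
    grid_size: int = 512,
    prominence_frac: float = 0.01,
) -> CutoffResult:
    """Expression cutoff from the pooled log2CPM distribution.

    Locates the density minimum between the two most prominent modes of a
    Silverman-bandwidth KDE.  When the distribution is not bimodal, falls
    back to the 5th percentile (flagged in the result).  A manual cutoff
    always wins.
    """
    if manual is not None:
        return CutoffResult(float(manual), "manual")
    arr = np.asarray(values, dtype=float).ravel()
    arr = arr[np.isfinite(arr)]
    if arr.size < 100:
        raise ValueError(
            f"need at least 100 finite log2CPM values to place a cutoff (got {arr.size}); "
            "pass a manual cutoff instead"
        )
    kde = gaussian_kde(arr, bw_method=bw_method)
    grid = np.linspace(arr.min(), arr.max(), grid_size)
    dens = kde(grid)
    peaks, _ = find_peaks(dens, prominence=prominence_frac * dens.max())
    if peaks.size < 2:
        return CutoffResult(float(np.percentile(arr, 5)), "percentile-fallback")
    # two most prominent modes, in position order
    order = np.argsort(dens[peaks])[::-1][:2]
    left, right = sorted(peaks[order])
    valley = left + int(np.argmin(dens[left : right + 1]))
    return CutoffResult(float(grid[valley]), "valley")


def expressed_genes(
    log2cpm_values: pd.DataFrame,
    cutoff: float,
    min_samples: int = 3,
) -> ExpressionCallSet:
    """Flag genes with log2CPM above ``cutoff`` in ≥ ``min_samples`` samples."""
    n_samples = log2cpm_values.shape[1]
    if not 1 <= min_samples <= n_samples:
        raise ValueError(
            f"min_samples must lie in [1, {n_samples}] (got {min_samples})"
        )
    exceed = (log2cpm_values > cutoff).sum(axis=1)
    return ExpressionCallSet(expressed=exceed >= min_samples, cutoff=float(cutoff), min_samples=min_samples)


def pathway_coverage(
    calls: ExpressionCallSet,
    pathway_map: pd.DataFrame,
    complete_threshold: float = 0.75,
) -> pd.DataFrame:
    """Coverage ratio of each pathway within each genome.

    ``pathway_map`` has columns ``pathway`` and ``gene`` (one row per
    membership) and optionally ``genome``; each genome's pathway is scored
    against its own gene universe.  Ratio = expressed genes / pathway genes.
    Status: ``complete`` at/above ``complete_threshold``, ``absent`` at
    exactly zero, ``incomplete`` in between.
    """
    required = {"pathway", "gene"}
    missing = required - set(pathway_map.columns)
    if missing:
        raise ValueError(f"pathway map missing columns: {sorted(missing)}")
    pm = pathway_map.copy()
    if "genome" not in pm.columns:
        pm["genome"] = "genome"
    if pm["gene"].isna().any():
        bad = pm.loc[pm["gene"].isna(), "pathway"].unique()
        raise ValueError(f"pathway(s) with missing genes: {', '.join(map(str, bad))}")
    expressed_set = calls.expressed_set
    rows = []
    for (genome, pathway), grp in pm.groupby(["genome", "pathway"], sort=True):
        genes = set(grp["gene"])
        if not genes:
            raise ValueError(f"pathway {pathway!r} in genome {genome!r} has no genes")
        n_expr = len(genes & expressed_set)
        ratio = n_expr / len(genes)
        if ratio == 0:
            status = ABSENT
        elif ratio >= complete_threshold:
            status = COMPLETE
        else:
            status = INCOMPLETE
        rows.append(
            {
                "genome": genome,
                "pathway": pathway,
                "n_expressed": n_expr,
                "n_genes": len(genes),
                "ratio": ratio,
                "status": status,
            }
        )
    return pd.DataFrame(rows)
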
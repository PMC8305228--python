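"""Optional boxplot output for per-taxon labeling patterns (cosmetic)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_taxon_ria(per_peptide: pd.DataFrame, path: str | Path, condition: str | None = None) -> None:
    """Boxplots of per-peptide RIA by genus and timepoint for one condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = per_peptide
    if condition is not None:
        df = df[df["condition"] == condition]
    timepoints = sorted(df["timepoint"].unique())
    fig, axes = plt.subplots(1, len(timepoints), figsize=(4 * len(timepoints), 4), sharey=True)
    if len(timepoints) == 1:
        axes = [axes]
    for ax, t in zip(axes, timepoints):
        sub = df[df["timepoint"] == t]
        groups = [g["ria_percent"].dropna().to_numpy() for _, g in sub.groupby("genus")]
        names = [name for name, _ in sub.groupby("genus")]
        ax.boxplot(groups, tick_labels=names, whis=1.5)
        ax.set_title(f"{t:g} days")
        ax.set_ylabel("RIA (%)")
        ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
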
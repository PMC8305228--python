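"""Readers and writers for the pipeline's delimited-text tables.

All tables are UTF-8 with a mandatory header row; tab-delimited by default,
comma accepted (auto-detected from the header line).  Peptide envelope
intensities may be supplied wide (columns ``i0, i1, ...``) or long
(columns ``peptide``/key columns + ``offset`` + ``intensity``); long input
is pivoted to wide on read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .isotopes import IsotopeAbundanceTable

__all__ = [
    "read_table",
    "write_table",
    "read_peptide_table",
    "read_count_matrix",
    "read_pathway_map",
    "read_isotope_table",
    "write_isotope_table",
]


def _sniff_sep(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if "\t" in header else ","


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    return pd.read_csv(path, sep=_sniff_sep(path))


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)


def _envelope_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("i") and c[1:].isdigit()]
    return sorted(cols, key=lambda c: int(c[1:]))


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Read a peptide observation table, wide or long, into wide format."""
    df = read_table(path)
    if "peptide" not in df.columns:
        raise ValueError(f"{path}: peptide table must have a 'peptide' column")
    if _envelope_columns(df):
        return df
    if {"offset", "intensity"} <= set(df.columns):
        keys = [c for c in df.columns if c not in ("offset", "intensity")]
        wide = df.pivot_table(
            index=keys, columns="offset", values="intensity", fill_value=0.0
        )
        wide.columns = [f"i{int(c)}" for c in wide.columns]
        return wide.reset_index()
    raise ValueError(
        f"{path}: expected wide envelope columns (i0, i1, ...) or long-format "
        "'offset'/'intensity' columns"
    )


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Genes × samples count matrix; first column holds gene identifiers."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count matrix not found: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: count matrix has no sample columns")
    return df


def read_pathway_map(path: str | Path) -> pd.DataFrame:
    """Pathway membership map with columns pathway, gene[, genome]."""
    df = read_table(path)
    missing = {"pathway", "gene"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: pathway map missing columns {sorted(missing)}")
    return df


def read_isotope_table(path: str | Path) -> IsotopeAbundanceTable:
    with Path(path).open("r", encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh)
    return IsotopeAbundanceTable.from_dict(mapping)


def write_isotope_table(table: IsotopeAbundanceTable, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(table.to_dict(), fh)
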
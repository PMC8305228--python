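"""Peptide elemental composition and isotopologue envelope models.

A peptide measured by MS1 appears as a series of peaks separated by one
neutron mass — the isotopologue envelope.  Under stable isotope probing
with ¹³CO₂, the carbon atoms of newly synthesised protein carry an
elevated ¹³C fraction (the relative isotope abundance, RIA), which shifts
and broadens the envelope.  This module computes theoretical envelopes for
arbitrary elemental compositions: carbon follows a binomial over
{¹²C, ¹³C} with a configurable success probability, every other element
follows its natural multi-isotope distribution, and the per-element
distributions are combined by exact discrete convolution over integer
neutron-count offsets (offset 0 = monoisotopic peak).

Charge affects only m/z spacing, never the offset-indexed envelope, so
protons are excluded from compositions throughout.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _ptmass
from scipy import stats as _stats

__all__ = [
    "STANDARD_RESIDUES",
    "NATURAL_C13",
    "IsotopeAbundanceTable",
    "IsotopologueEnvelope",
    "NATURAL_ABUNDANCE",
    "composition_from_sequence",
    "parse_modifications",
    "envelope",
    "mixture_envelope",
    "centroid",
]

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: Natural heavy-carbon fraction (¹³C ≈ 1.1 %).
NATURAL_C13 = 0.011

# Composition deltas for the two modifications routinely set in database
# searches of SIP experiments.  Carbamidomethylation of Cys adds C2H3NO;
# oxidation of Met adds one O.
_MODIFICATIONS: dict[str, dict[str, int]] = {
    "carbamidomethyl": {"C": 2, "H": 3, "N": 1, "O": 1},
    "cam": {"C": 2, "H": 3, "N": 1, "O": 1},
    "oxidation": {"O": 1},
    "ox": {"O": 1},
}

# Natural isotope abundances by integer neutron offset (IUPAC representative
# values; carbon fixed at the 1.1 % heavy fraction used for natural-abundance
# RIA).  Each element's fractions sum to 1.
_DEFAULT_ABUNDANCES: tuple[tuple[str, tuple[tuple[int, float], ...]], ...] = (
    ("C", ((0, 1.0 - NATURAL_C13), (1, NATURAL_C13))),
    ("H", ((0, 0.999885), (1, 0.000115))),
    ("N", ((0, 0.99636), (1, 0.00364))),
    ("O", ((0, 0.99757), (1, 0.00038), (2, 0.00205))),
    ("S", ((0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001))),
)


@dataclass(frozen=True)
class IsotopeAbundanceTable:
    """Per-element isotope distributions over integer neutron offsets.

    ``data`` maps each element symbol to an ordered tuple of
    ``(offset, abundance)`` pairs.  Abundances per element must sum to 1
    within 1e-12.  The table is hashable so model envelopes can be cached.
    """

    data: tuple[tuple[str, tuple[tuple[int, float], ...]], ...] = _DEFAULT_ABUNDANCES
    _vectors: dict = field(default=None, compare=False, repr=False, hash=False)

    def __post_init__(self) -> None:
        vectors: dict[str, np.ndarray] = {}
        for element, pairs in self.data:
            offsets = np.array([o for o, _ in pairs], dtype=int)
            fracs = np.array([f for _, f in pairs], dtype=float)
            if (offsets < 0).any():
                raise ValueError(f"negative isotope offset for element {element}")
            if ((fracs < 0) | (fracs > 1)).any():
                raise ValueError(f"isotope abundances of {element} outside [0, 1]")
            if abs(fracs.sum() - 1.0) > 1e-12:
                raise ValueError(
                    f"isotope abundances of {element} sum to {fracs.sum()!r}, not 1"
                )
            vec = np.zeros(int(offsets.max()) + 1)
            vec[offsets] = fracs
            vectors[element] = vec
        object.__setattr__(self, "_vectors", vectors)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(e for e, _ in self.data)

    @property
    def natural_c13(self) -> float:
        """Natural heavy-isotope fraction of carbon."""
        vec = self._vectors["C"]
        return float(vec[1:].sum())

    def single_atom(self, element: str) -> np.ndarray:
        """Isotope distribution of a single atom, indexed by neutron offset."""
        try:
            return self._vectors[element].copy()
        except KeyError:
            raise KeyError(f"element {element!r} not present in isotope table") from None

    def with_c13(self, c13_fraction: float) -> "IsotopeAbundanceTable":
        """Return a table whose carbon heavy fraction is ``c13_fraction``."""
        if not 0.0 <= c13_fraction <= 1.0:
            raise ValueError("c13_fraction must lie in [0, 1]")
        rows = tuple(
            (e, ((0, 1.0 - c13_fraction), (1, c13_fraction))) if e == "C" else (e, p)
            for e, p in self.data
        )
        return IsotopeAbundanceTable(rows)

    def to_dict(self) -> dict:
        return {e: [[int(o), float(f)] for o, f in pairs] for e, pairs in self.data}

    @classmethod
    def from_dict(cls, mapping: dict) -> "IsotopeAbundanceTable":
        rows = tuple(
            (str(e), tuple((int(o), float(f)) for o, f in pairs))
            for e, pairs in mapping.items()
        )
        return cls(rows)


#: Shipped default natural-abundance table.
NATURAL_ABUNDANCE = IsotopeAbundanceTable()


@dataclass(frozen=True)
class IsotopologueEnvelope:
    """Relative intensities of a peptide's isotopologues by neutron offset.

    ``intensities[k]`` is the (relative or raw) intensity at ``k`` neutrons
    above the monoisotopic peak.  ``captured`` records the fraction of total
    model probability retained after truncation.
    """

    intensities: np.ndarray
    normalized: bool = True
    captured: float = 1.0
    peptide_id: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("envelope intensities must be a non-empty 1-D vector")
        if (arr < 0).any():
            raise ValueError("envelope intensities must be non-negative")
        if self.normalized and abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError("normalized envelope must sum to 1 within 1e-9")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "intensities", arr)

    def __len__(self) -> int:
        return int(self.intensities.size)


def parse_modifications(text: str | None) -> dict[str, int]:
    """Parse a modification string like ``"carbamidomethyl:2; oxidation"``.

    Tokens are separated by ``;`` or ``,``; each is ``name`` or ``name:count``.
    Names are case-insensitive; ``cam`` and ``ox`` are accepted aliases.
    """
    counts: dict[str, int] = {"C": 0, "H": 0, "N": 0, "O": 0, "S": 0}
    if text is None or not str(text).strip() or str(text).lower() == "nan":
        return counts
    for token in str(text).replace(";", ",").split(","):
        token = token.strip()
        if not token:
            continue
        name, _, mult = token.partition(":")
        name = name.strip().lower()
        if name not in _MODIFICATIONS:
            raise ValueError(f"unknown modification {name!r}")
        k = int(mult) if mult.strip() else 1
        if k < 0:
            raise ValueError("modification count must be non-negative")
        for el, n in _MODIFICATIONS[name].items():
            counts[el] += k * n
    return counts


def composition_from_sequence(
    peptide: str, modifications: str | None = None
) -> _ptmass.Composition:
    """Elemental composition (CHNOS) of a neutral peptide.

    The composition is the sum of residue compositions plus one water.
    ``modifications`` optionally adds fixed/variable modification atoms
    (see :func:`parse_modifications`).
    """
    if not isinstance(peptide, str) or len(peptide) < 1:
        raise ValueError("peptide must be a non-empty amino-acid string")
    bad = sorted(set(peptide) - STANDARD_RESIDUES)
    if bad:
        raise ValueError(
            f"peptide {peptide!r} contains non-standard residue letter(s): "
            + ", ".join(repr(b) for b in bad)
        )
    comp = _ptmass.Composition(sequence=peptide)
    for el, n in parse_modifications(modifications).items():
        if n:
            comp[el] = comp.get(el, 0) + n
    return comp


def _composition_key(comp) -> tuple[tuple[str, int], ...]:
    items = tuple(sorted((str(e), int(n)) for e, n in dict(comp).items() if n))
    if not items:
        raise ValueError("empty elemental composition")
    if any(n < 0 for _, n in items):
        raise ValueError("element counts must be non-negative")
    return items


def _self_convolve(vec: np.ndarray, n: int) -> np.ndarray:
    """n-fold convolution of a single-atom distribution (binary exponentiation)."""
    result = np.array([1.0])
    base = vec
    while n > 0:
        if n & 1:
            result = np.convolve(result, base)
        n >>= 1
        if n:
            base = np.convolve(base, base)
    return result


@functools.lru_cache(maxsize=100_000)
def _envelope_vector(
    comp_key: tuple[tuple[str, int], ...],
    c13_fraction: float,
    table: IsotopeAbundanceTable,
    truncation: float,
) -> tuple[np.ndarray, float]:
    dist = np.array([1.0])
    for element, count in comp_key:
        if element == "C":
            part = _stats.binom.pmf(np.arange(count + 1), count, c13_fraction)
        else:
            part = _self_convolve(table.single_atom(element), count)
        dist = np.convolve(dist, part)
    total = dist.sum()
    if total <= 0:
        raise ValueError("degenerate composition: zero total probability")
    dist = dist / total
    cum = np.cumsum(dist)
    cut = int(np.searchsorted(cum, 1.0 - truncation) + 1)
    kept = dist[:cut]
    captured = float(kept.sum())
    kept = kept / captured
    kept.setflags(write=False)
    return kept, captured


def envelope(
    comp,
    c13_fraction: float | None = None,
    table: IsotopeAbundanceTable = NATURAL_ABUNDANCE,
    truncation: float = 1e-6,
    peptide_id: str | None = None,
) -> IsotopologueEnvelope:
    """Theoretical isotopologue envelope of a composition.

    Carbon atoms follow ``Binomial(n_C, c13_fraction)``; other elements
    follow their natural distributions from ``table``; the per-element
    distributions are convolved, truncated once cumulative probability
    reaches ``1 - truncation``, and renormalized.

    Parameters
    ----------
    comp : mapping element -> atom count (e.g. ``pyteomics.mass.Composition``)
    c13_fraction : heavy-carbon success probability; defaults to the table's
        natural value (≈ 0.011).
    """
    if c13_fraction is None:
        c13_fraction = table.natural_c13
    if not 0.0 <= c13_fraction <= 1.0:
        raise ValueError("c13_fraction must lie in [0, 1]")
    if not 0.0 < truncation < 1.0:
        raise ValueError("truncation must lie in (0, 1)")
    key = _composition_key(comp)
    vec, captured = _envelope_vector(key, float(c13_fraction), table, float(truncation))
    return IsotopologueEnvelope(vec, normalized=True, captured=captured, peptide_id=peptide_id)


def mixture_envelope(
    comp,
    ria: float,
    f_labeled: float,
    table: IsotopeAbundanceTable = NATURAL_ABUNDANCE,
    truncation: float = 1e-6,
    peptide_id: str | None = None,
) -> IsotopologueEnvelope:
    """Two-population envelope: unlabeled (natural) plus labeled at ``ria``.

    Returns ``(1 - f_labeled) * natural + f_labeled * labeled``, normalized.
    ``ria`` is the labeled population's ¹³C fraction and may not fall below
    natural abundance (biomass cannot be less labeled than its substrate).
    """
    natural = table.natural_c13
    if ria < natural - 1e-12 or ria > 1.0:
        raise ValueError(
            f"ria must lie in [{natural}, 1] (got {ria!r}); labeled carbon cannot "
            "be below natural abundance"
        )
    if not 0.0 <= f_labeled <= 1.0:
        raise ValueError("f_labeled must lie in [0, 1]")
    unl = envelope(comp, natural, table, truncation)
    lab = envelope(comp, ria, table, truncation)
    size = max(len(unl), len(lab))
    mix = np.zeros(size)
    mix[: len(unl)] += (1.0 - f_labeled) * unl.intensities
    mix[: len(lab)] += f_labeled * lab.intensities
    mix /= mix.sum()
    captured = (1.0 - f_labeled) * unl.captured + f_labeled * lab.captured
    return IsotopologueEnvelope(mix, normalized=True, captured=captured, peptide_id=peptide_id)


def centroid(env: IsotopologueEnvelope | np.ndarray) -> float:
    """Mean neutron offset of an envelope (intensity-weighted)."""
    arr = env.intensities if isinstance(env, IsotopologueEnvelope) else np.asarray(env, float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("cannot take centroid of an all-zero envelope")
    return float(np.arange(arr.size) @ arr / total)
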
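"""Synthetic ¹³CO₂-microcosm datasets with known ground truth.

Emulates the labeling experiment end to end: a community of genera with
trophic classes (a chemolithoautotroph incorporating carbon near tracer
enrichment, cross-feeders at intermediate ¹³C, inactive organisms at
natural abundance) grows exponentially with configurable generation times;
triplicate microcosms are sampled at 7, 14 and 28 days; each observed
peptide envelope is the two-population mixture model evaluated at the
genus's true labeled fraction f = 1 − 2^(−t/td), scaled by a random total
intensity and degraded by multiplicative log-normal noise per offset.

Also generates bimodal count matrices (silent vs expressed genes) for the
expression-cutoff procedures, again with recorded truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .growth import AUTOTROPH, CROSSFED, INACTIVE
from .isotopes import NATURAL_ABUNDANCE, IsotopeAbundanceTable, composition_from_sequence, mixture_envelope

__all__ = [
    "GenusSpec",
    "CommunityScenario",
    "default_scenario",
    "peptides_from_fasta",
    "random_tryptic_peptide",
    "simulate_peptides",
    "simulate_labeled_envelopes",
    "simulate_counts",
]

# Interior residues exclude K/R so sequences look fully cleaved (tryptic).
_INTERIOR = np.array(list("ACDEFGHILMNPQSTVWY"))
_TERMINAL = np.array(list("KR"))


@dataclass(frozen=True)
class GenusSpec:
    """One genus of the simulated community.

    ``substrate_c13`` is the ¹³C fraction of the carbon the genus actually
    assimilates: for cross-feeders it must be supplied (intermediate between
    natural abundance and tracer enrichment); autotrophs use the tracer
    itself; inactive genera ignore it.
    """

    name: str
    trophic_class: str  # autotroph | crossfed_heterotroph | inactive
    generation_time: float | None = None  # days; None for inactive
    substrate_c13: float | None = None


@dataclass(frozen=True)
class CommunityScenario:
    """Study conditions of a simulated microcosm incubation."""

    genera: tuple[GenusSpec, ...]
    tracer_enrichment: float = 0.99
    timepoints: tuple[float, ...] = (7.0, 14.0, 28.0)
    replicates: int = 3
    peptides_per_genus: int = 20
    noise_cv: float = 0.02
    intensity_median: float = 1e6
    intensity_sigma: float = 1.0  # log-scale spread of total peptide intensity
    condition: str = "oxic"
    peptide_pool: tuple[str, ...] | None = None  # e.g. from peptides_from_fasta
    seed: int = 0


def default_scenario(seed: int = 0, **overrides) -> CommunityScenario:
    """Microcosm-like community: one fast and one slow chemolithoautotroph
    (generation times 6 and 16 days), two cross-fed heterotrophs at
    intermediate ¹³C, and two inactive genera."""
    genera = (
        GenusSpec("Ferrovum", AUTOTROPH, generation_time=6.0),
        GenusSpec("Leptospirillum", AUTOTROPH, generation_time=16.0),
        GenusSpec("Acidiphilium", CROSSFED, generation_time=14.0, substrate_c13=0.028),
        GenusSpec("Acidocella", CROSSFED, generation_time=12.0, substrate_c13=0.027),
        GenusSpec("Acidithrix", INACTIVE),
        GenusSpec("Granulicella", INACTIVE),
    )
    return replace(CommunityScenario(genera=genera, seed=seed), **overrides)


def _validate(scenario: CommunityScenario, natural: float) -> None:
    if not natural < scenario.tracer_enrichment <= 1.0:
        raise ValueError("tracer enrichment must lie in (natural, 1]")
    if scenario.replicates < 1 or scenario.peptides_per_genus < 1:
        raise ValueError("replicates and peptides_per_genus must be >= 1")
    if any(t <= 0 for t in scenario.timepoints):
        raise ValueError("timepoints must be positive incubation spans (days)")
    for g in scenario.genera:
        if g.trophic_class not in (AUTOTROPH, CROSSFED, INACTIVE):
            raise ValueError(f"unknown trophic class {g.trophic_class!r} for {g.name}")
        if g.trophic_class != INACTIVE and not (g.generation_time and g.generation_time > 0):
            raise ValueError(f"growing genus {g.name} needs a positive generation time")
        if g.trophic_class == CROSSFED:
            if g.substrate_c13 is None or g.substrate_c13 < natural:
                raise ValueError(
                    f"cross-feeder {g.name} needs a substrate 13C fraction at or "
                    "above natural abundance"
                )


def _envelope_frame(envelopes: list[np.ndarray]) -> pd.DataFrame:
    """Stack variable-length envelopes into zero-padded wide columns i0..iK."""
    width = max(e.size for e in envelopes)
    mat = np.zeros((len(envelopes), width))
    for i, e in enumerate(envelopes):
        mat[i, : e.size] = e
    return pd.DataFrame(mat, columns=[f"i{k}" for k in range(width)])


def random_tryptic_peptide(rng: np.random.Generator, min_len: int = 8, max_len: int = 25) -> str:
    """Random tryptic-like peptide: 8–25 residues, ending in K or R."""
    length = int(rng.integers(min_len, max_len + 1))
    body = rng.choice(_INTERIOR, size=length - 1)
    return "".join(body) + str(rng.choice(_TERMINAL))


def peptides_from_fasta(
    path, min_len: int = 8, max_len: int = 25
) -> tuple[str, ...]:
    """Fully cleaved tryptic peptides from a protein FASTA file.

    Returns the sorted unique peptides of usable length composed of the 20
    standard residues, for use as a scenario ``peptide_pool``.
    """
    from pyteomics import fasta, parser

    from .isotopes import STANDARD_RESIDUES

    peptides: set[str] = set()
    for _, seq in fasta.read(str(path)):
        for pep in parser.cleave(seq, parser.expasy_rules["trypsin"], missed_cleavages=0):
            if min_len <= len(pep) <= max_len and set(pep) <= STANDARD_RESIDUES:
                peptides.add(pep)
    if not peptides:
        raise ValueError(f"{path}: no usable tryptic peptides of length {min_len}-{max_len}")
    return tuple(sorted(peptides))


def _draw_peptide(rng: np.random.Generator, scenario: CommunityScenario) -> str:
    if scenario.peptide_pool is not None:
        return str(rng.choice(np.asarray(scenario.peptide_pool, dtype=object)))
    return random_tryptic_peptide(rng)


def _noisy_envelope(
    model: np.ndarray,
    total: float,
    noise_cv: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if noise_cv <= 0:
        return model * total
    sigma = np.sqrt(np.log1p(noise_cv**2))
    factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=model.size)
    return model * total * factors


def simulate_peptides(
    scenario: CommunityScenario,
    table: IsotopeAbundanceTable = NATURAL_ABUNDANCE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a peptide observation table plus its ground truth.

    For each genus × timepoint × replicate, ``peptides_per_genus`` random
    tryptic peptides are drawn; the labeled fraction follows exponential
    growth, f = 1 − 2^(−t/td); the labeled population's ¹³C fraction is the
    tracer enrichment (autotrophs) or the substrate fraction (cross-feeders);
    inactive genera stay at natural abundance.  Observed envelopes are
    mixture-model envelopes times a log-normal total intensity with
    multiplicative log-normal noise per offset.  Deterministic per seed.

    Returns ``(observations, truth)``; observations carry wide envelope
    columns ``i0..iK`` (rows padded with zeros to the longest envelope).
    """
    natural = table.natural_c13
    _validate(scenario, natural)
    rng = np.random.default_rng(scenario.seed)
    obs_rows: list[dict] = []
    truth_rows: list[dict] = []
    envelopes: list[np.ndarray] = []
    for genus in scenario.genera:
        for t in scenario.timepoints:
            for rep in range(1, scenario.replicates + 1):
                for _ in range(scenario.peptides_per_genus):
                    pep = _draw_peptide(rng, scenario)
                    if genus.trophic_class == INACTIVE:
                        f, ria = 0.0, natural
                    else:
                        f = 1.0 - 2.0 ** (-t / genus.generation_time)
                        ria = (
                            scenario.tracer_enrichment
                            if genus.trophic_class == AUTOTROPH
                            else genus.substrate_c13
                        )
                    comp = composition_from_sequence(pep)
                    model = mixture_envelope(comp, ria, f, table).intensities
                    total = float(
                        rng.lognormal(np.log(scenario.intensity_median), scenario.intensity_sigma)
                    )
                    observed = _noisy_envelope(model, total, scenario.noise_cv, rng)
                    meta = {
                        "peptide": pep,
                        "modifications": "",
                        "charge": 2,
                        "sample": f"{scenario.condition}_T{t:g}_R{rep}",
                        "condition": scenario.condition,
                        "timepoint": t,
                        "replicate": rep,
                        "genus": genus.name,
                        "ko": "",
                    }
                    obs_rows.append(meta)
                    envelopes.append(observed)
                    truth_rows.append(
                        {
                            **meta,
                            "true_ria_percent": ria * 100.0,
                            "true_f_labeled": f,
                            "true_I12C": (1.0 - f) * total,
                            "true_I13C": f * total,
                            "trophic_class": genus.trophic_class,
                            "true_td": genus.generation_time
                            if genus.trophic_class != INACTIVE
                            else np.nan,
                            "seed": scenario.seed,
                        }
                    )
    obs = pd.concat([pd.DataFrame(obs_rows), _envelope_frame(envelopes)], axis=1)
    return obs, pd.DataFrame(truth_rows)


def simulate_labeled_envelopes(
    n_peptides: int,
    ria: float,
    f_labeled: float,
    noise_cv: float = 0.02,
    seed: int = 0,
    table: IsotopeAbundanceTable = NATURAL_ABUNDANCE,
) -> pd.DataFrame:
    """Envelopes of random tryptic peptides at one (ria, f_labeled) setting.

    Convenience generator for estimator benchmarking: returns a wide-format
    observation table with known uniform truth.
    """
    rng = np.random.default_rng(seed)
    rows, envelopes = [], []
    for i in range(n_peptides):
        pep = random_tryptic_peptide(rng)
        comp = composition_from_sequence(pep)
        model = mixture_envelope(comp, ria, f_labeled, table).intensities
        total = float(rng.lognormal(np.log(1e6), 1.0))
        envelopes.append(_noisy_envelope(model, total, noise_cv, rng))
        rows.append({"peptide": pep, "modifications": "", "charge": 2})
    return pd.concat([pd.DataFrame(rows), _envelope_frame(envelopes)], axis=1)


def simulate_counts(
    n_genes: int = 2000,
    n_samples: int = 6,
    expressed_fraction: float = 0.5,
    mode_separation: float = 6.0,
    seed: int = 0,
    silent_mode_log2cpm: float = -2.0,
    mode_sd: float = 0.8,
    dispersion_size: float = 10.0,
) -> tuple[pd.DataFrame, set, list[str]]:
    """Bimodal synthetic count matrix with a known expressed gene set.

    Silent genes sit at a low log2CPM mode, expressed genes
    ``mode_separation`` log2 units higher; per-gene expected CPM values are
    converted to expected counts under per-sample library sizes varying at
    most 3-fold, then drawn from an overdispersed (gamma-Poisson) model.

    Returns ``(counts, true_expressed_set, warnings)``.
    """
    if n_genes < 100:
        raise ValueError("need at least 100 genes for a usable count matrix")
    if mode_separation <= 0:
        raise ValueError("mode separation must be positive")
    warnings: list[str] = []
    if expressed_fraction in (0.0, 1.0):
        warnings.append(
            "degenerate expressed fraction: pooled log2CPM will be unimodal and "
            "valley detection downstream will fall back to a percentile"
        )
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    n_expr = int(round(expressed_fraction * n_genes))
    is_expr = np.zeros(n_genes, dtype=bool)
    is_expr[rng.choice(n_genes, size=n_expr, replace=False)] = True
    mode = np.where(is_expr, silent_mode_log2cpm + mode_separation, silent_mode_log2cpm)
    gene_log2cpm = rng.normal(mode, mode_sd)
    libsizes = rng.uniform(1e6, 3e6, size=n_samples)
    expected = (2.0**gene_log2cpm)[:, None] / 1e6 * libsizes[None, :]
    lam = rng.gamma(shape=dispersion_size, scale=expected / dispersion_size)
    counts = rng.poisson(lam)
    df = pd.DataFrame(counts, index=genes, columns=[f"S{j+1}" for j in range(n_samples)])
    truth = {g for g, e in zip(genes, is_expr) if e}
    return df, truth, warnings
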
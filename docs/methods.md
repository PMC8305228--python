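# Methods

## Isotopologue envelope model

A peptide's MS1 isotopologue envelope is represented on integer neutron
offsets k = 0, 1, 2, … above the monoisotopic peak (aggregated
isotopologues, not fine structure).  This matches how SIP envelopes are
read from centroided MS1 data and keeps the arithmetic exact: for an
elemental composition {C: n_C, H: n_H, N, O, S}, each element contributes
the n-fold discrete self-convolution of its single-atom isotope
distribution, and the envelope is the convolution across elements.
Carbon is special: its heavy fraction p is the free parameter (the ¹³C
enrichment), so the carbon factor is Binomial(n_C, p).  Compositions come
from pyteomics (residue sums plus one water); carbamidomethylation
(+C2H3NO per Cys) and methionine oxidation (+O) are supported as optional
modification strings.  Charge state changes only m/z spacing and is
excluded from the model.

Natural abundances ship in one editable table (YAML-serializable):
¹³C = 1.1 % (the natural-abundance reference value used throughout),
H/N/O/S from standard IUPAC representative values.  Envelopes are
truncated once cumulative probability reaches 1 − 1e-6 (configurable) and
renormalized; the captured fraction is recorded.

Correctness is checked against an exhaustive enumeration oracle (every
isotope placement over every atom, ≤ 7 atoms) to 1e-12 per offset.

## Two-population mixture and RIA estimation

The labeling model assumes exactly one labeled subpopulation per peptide:
protein made before tracer addition sits at natural abundance, protein
made during the incubation carries carbon at the relative isotope
abundance (RIA) of the organism's substrate.  The observed envelope is

    y ≈ (1 − f) · E(natural) + f · E(ria)

with f the labeled fraction of total signal.  The fit minimizes a
chi-square discrepancy on normalized intensities over the observed
offsets (cosine distance is available behind a config switch for
sensitivity checks).  Optimization is deterministic: a coarse grid on ria
(step 0.005 over [0.011, 0.999]) with f profile-solved at each grid point
by bound-constrained least squares (a closed-form projection onto [0, 1],
since the model is linear in f), followed by bounded scalar refinement
(xatol 1e-9) around the grid optimum.  No random initialization.

Reported intensities are I12C = (1 − f)·total and I13C = f·total, so
conservation I12C + I13C = total holds by construction.  A labeled
component counts as detected only if it reduces chi-square by ≥ 5 %
versus the natural-only model; otherwise the peptide is reported at
natural abundance (ria 1.1 %, f 0) and flagged `low-signal`.  This keeps
the natural-abundance null unbiased: pure-natural envelopes under noise
report exactly 1.1 % rather than accumulating small positive ria.

### Monoisotopic deconvolution for overlapping envelopes

At low enrichment the labeled envelope overlaps the natural one and the
mixture decomposition of intensities becomes ill-conditioned at offset
level.  In that regime the unlabeled abundance is taken from the
monoisotopic peak alone: only the unlabeled population contributes
appreciably at offset 0, so I12C = I(0) / p0 with p0 the natural
monoisotopic probability; I13C is the remainder.  I12C may not exceed the
observed total; a violation is flagged `overlap-inconsistent`, never
silently truncated.  The RIA itself is still the mixture fit's estimate
(the deconvolution only re-derives the intensity split); if the mixture
fit detected no labeled component the RIA is flagged `ria-undetermined`.

Method selection: the deconvolution is used when the labeled model
envelope places more than 10 % of its mass on offsets where the natural
envelope exceeds 1e-3; otherwise the mixture fit's intensity split is
kept.  Both estimators agree on I12C within 2 % when the envelopes are
disjoint (tested).

## Growth kinetics and activity classes

Doublings over an incubation of Δt days: n = log2((I12C + I13C)/I12C);
generation time td = Δt/n.  I12C = 0 (complete turnover) yields an
undefined n, and n = 0 an undefined td — both are NaN with explicit
flags rather than infinities, so downstream medians skip non-growing
peptides deliberately.

Activity classes from RIA in percent: strictly above 90 % ⇒ autotroph;
within ±0.5 points of 1.1 % ⇒ inactive; between ⇒ cross-fed heterotroph.
The 90 % boundary itself goes to the cross-fed class ("above" read as
strict) and the 0.5-point inactive tolerance is a package choice (no
instrument-level tolerance is standard); both are configurable.  RIA
below 1.1 % minus the tolerance is physically impossible for biomass and
is flagged `sub-natural`.

Per-taxon generation times are the median of peptide-level td values
(not td of pooled intensities): robust to ionization-efficiency
differences between peptides.  Taxon activity is the majority vote of
peptide calls, ties broken toward the less labeled class (conservative).

## Taxon summaries and rate arithmetic

Per (genus, condition, timepoint), RIA distributions are summarized with
Tukey boxplot statistics: quartiles by linear interpolation, whiskers at
the most extreme points within 1.5·IQR of the quartiles, outliers beyond.
Replicates are pooled.  Substrate consumption rates are minus the
least-squares slope of concentration versus time within a window;
fold-changes between windows are reported rounded the way such values are
conventionally printed (integer folds at/above 10, one decimal below)
with the raw ratio retained.

## Expression profiling

log2CPM = log2((count + pc) / (libsize + 2·pc) × 10⁶) with pseudo-count
pc = 0.5 by default (pc = 0 reproduces the textbook definition but maps
zeros to −inf).  This explicit formula is used rather than edgeR's
prior-count scaling so the values are exactly reproducible from the
definition.

The expression cutoff is placed at the density minimum between the
low-abundance mode and the main expression mode of the pooled log2CPM
distribution: Gaussian KDE with Silverman's bandwidth on a 512-point
grid, modes found by peak detection (prominence ≥ 1 % of the density
maximum), valley = density argmin between the two most prominent modes.
"Lowest values between the modes" is an interpretation of visual cutoff
placement, so the result records its method; if no second mode exists the
cutoff falls back to the 5th percentile (flagged), and a manual cutoff
always wins.  A gene is expressed if it exceeds the cutoff in at least 3
samples (configurable).

Pathway coverage = expressed genes / pathway genes, computed per genome
against that genome's own gene universe.  Status thresholds (not a
community standard, configurable): complete at ratio ≥ 0.75, absent at
exactly 0, incomplete between.

## Synthetic data generator

The generator emulates the ¹³CO₂ microcosm design: genera with trophic
classes, exponential growth so the labeled fraction at time t is
f = 1 − 2^(−t/td), sampling at 7/14/28 days in triplicate.  The labeled
population's RIA is the tracer enrichment for autotrophs (default 0.99 —
the tracer purity is a free parameter, not an asserted experimental
value) and a configurable substrate ¹³C fraction for cross-feeders
(defaults near 2.7–2.8 %, the intermediate enrichment regime);
inactive genera stay at natural abundance.  Peptides are random
tryptic-like sequences (8–25 residues, K/R C-terminus, no internal K/R).
Observed envelopes are forward-model envelopes times a log-normal total
intensity (median 1e6, sigma 1) with mean-one multiplicative log-normal
noise per offset (CV 2 % by default — chosen for testability; no claim of
fidelity to any instrument's noise).  Everything is reproducible from the
scenario seed.

Count matrices: silent genes at a low log2CPM mode (−2), expressed genes
one mode-separation higher (default 6 log2 units), per-gene means jittered
(sd 0.8), counts drawn gamma-Poisson (size 10) under library sizes varying
≤ 3-fold.

What the generator does **not** emulate — and therefore what passing
tests do not demonstrate about real data: peptide identification errors
and chimeric spectra, retention-time-dependent intensity drift, isotope
dilution of the substrate pool over time, multiple labeled subpopulations
per peptide (e.g. mixed turnover cohorts), correlated noise across
offsets, and missing envelopes at low abundance.

## Numerical choices and degenerate inputs

* Envelopes are windowed to the observed offsets and renormalized there
  for fitting; truth beyond the observed window is treated as unobserved.
* Chi-square denominators are floored at 1e-10 to tolerate model zeros.
* A perfectly natural input has chi-square 0 against the null and is
  reported at 1.1 % via the low-signal rule, not via the optimizer.
* Zero-carbon compositions are rejected by the mixture fit (no labeling
  signal exists) and produce c13-independent envelopes in the model.
* All-zero envelopes, empty compositions, non-standard residues, zero
  library sizes, and empty pathways are rejected with the offending item
  named.

## Problem sizes used in the shipped checks

The test-suite simulations use 1000 natural-abundance replicates for the
estimator null, 4–6 peptides per (ria, f) cell over the 5×3 recovery
grid, 20 peptides per genus for generation-time recovery, and 1500–2000
genes × 6 samples for expression recovery.  These sizes give stable
medians for the quantities checked while keeping the default suite fast;
larger runs only tighten the same estimates.

## Known limitations

* One labeled subpopulation per peptide; multi-RIA mixtures are out of
  scope and will be averaged into a single (ria, f) pair.
* RIA resolution is bounded below by envelope counting statistics; at
  RIA within a few points of natural abundance the mixture fit and the
  low-signal rule trade sensitivity for null calibration.
* The monoisotopic deconvolution inherits the assumption that the labeled
  population contributes negligibly at offset 0; at very low RIA this
  biases I12C upward (the clamp and flags make this visible).
* The expression cutoff is only as good as the bimodality of the pooled
  distribution; strongly multi-modal data should use a manual cutoff.
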
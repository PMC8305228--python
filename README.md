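# sipquant

Protein stable-isotope-probing (protein-SIP) quantification for microbial
communities, plus metatranscriptome expression-cutoff profiling.

In a ¹³CO₂ labeling experiment, organisms that fix or consume
tracer-derived carbon build new protein whose carbon carries an elevated
¹³C fraction.  Mass spectrometry sees this as a shifted, broadened
isotopologue envelope for each peptide.  `sipquant` turns observed
envelopes into ecology:

* **Envelope model** — a peptide's theoretical isotopologue distribution
  for any elemental composition and any ¹³C enrichment: carbon follows
  Binomial(n_C, p), all other elements follow their natural isotope
  distributions, combined by exact discrete convolution over integer
  neutron offsets.
* **RIA estimation** — each observed envelope is fit as a two-population
  mixture, `(1 − f)·E(natural) + f·E(RIA)`, giving the labeled
  population's **relative isotope abundance** (RIA, the ¹³C fraction of
  its carbon), the labeled fraction `f`, and the unlabeled/labeled signal
  intensities I¹²C and I¹³C.  When the labeled and unlabeled envelopes
  overlap (low RIA), I¹²C is instead recovered from the monoisotopic peak
  via the natural monoisotopic probability.
* **Growth kinetics** — doublings `n = log2((I12C + I13C) / I12C)` and
  generation time `td = Δt / n` over the incubation span Δt.
* **Activity classes** — RIA > 90 % ⇒ autotroph (direct ¹³CO₂
  assimilation), RIA between 1.1 % and 90 % ⇒ heterotroph labeled by
  cross-feeding, RIA ≈ 1.1 % (natural abundance) ⇒ inactive.
* **Expression profiling** — log2 counts-per-million normalization of
  gene count matrices, an expression cutoff at the density valley of the
  bimodal pooled log2CPM distribution, the "expressed in ≥ 3 samples"
  rule, and per-genome pathway coverage ratios rendered
  complete / incomplete / absent.
* **Synthetic microcosms** — a generator that emulates the labeling
  experiment (trophic classes, exponential growth, triplicates at 7/14/28
  days, multiplicative envelope noise, bimodal count matrices) with full
  ground truth, so the whole pipeline is testable without any instrument
  data.

Intended users: microbial ecologists and proteomics bioinformaticians who
have per-peptide isotopologue intensities (and optionally gene count
tables) and want per-taxon activity, growth, and expressed-pathway calls.

## Worked example

```python
import numpy as np
from sipquant import (composition_from_sequence, mixture_envelope, PeptideObservation,
                      fit_mixture, doublings, generation_time, classify_activity)

# a tryptic peptide from a chemolithoautotroph after 7 days of 13CO2 labeling
peptide = "AVGDLEGTFSK"
comp = composition_from_sequence(peptide)
true_env = mixture_envelope(comp, ria=0.99, f_labeled=0.6).intensities
rng = np.random.default_rng(0)
observed = true_env * 2.0e6 * rng.lognormal(0, 0.02, true_env.size)  # noisy MS1

est = fit_mixture(PeptideObservation(peptide, observed), comp)
n = doublings(est.i12c, est.i13c)
td = generation_time(n, delta_t=7.0)
print(f"RIA       = {est.ria:.1f} %")
print(f"f_labeled = {est.f_labeled:.3f}")
print(f"doublings = {n:.3f}")
print(f"td        = {td:.2f} days")
print(f"activity  = {classify_activity(est.ria).label}")
```

Output:

```
RIA       = 99.0 %
f_labeled = 0.607
doublings = 1.347
td        = 5.20 days
activity  = autotroph
```

The fit recovers the simulated labeling state: the labeled population's
carbon is 99 % ¹³C (the tracer enrichment), about 60 % of the peptide
signal comes from protein synthesized during the incubation, which
corresponds to ~1.35 doublings in 7 days — a generation time of ~5 days —
and the RIA places the organism firmly in the autotroph class.

The same analysis runs from the shell on delimited tables:

```bash
sipq simulate --seed 42 --out-dir runs/sim            # synthetic microcosm + truth
sipq sip-fit  --peptides runs/sim/peptides.tsv --out-dir runs/fit
sipq sip-report --growth-table runs/fit/growth_table.tsv --out-dir runs/report
sipq expr-profile --counts runs/sim/counts.tsv --pathway-map map.tsv --out-dir runs/expr
```

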
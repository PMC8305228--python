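"""RIA estimation: mixture fit, monoisotopic deconvolution, method choice."""

import numpy as np
import pytest

from sipquant.isotopes import composition_from_sequence, envelope, mixture_envelope
from sipquant.quantify import (
    MIXTURE_FIT,
    MONO_DECONV,
    FitConfig,
    PeptideObservation,
    deconvolve_monoisotopic,
    estimate,
    fit_mixture,
    fit_peptide_table,
    select_method,
)
from sipquant.simulate import random_tryptic_peptide, simulate_labeled_envelopes

PEPTIDE = "ALDEFGHTSVMK"  # 12-residue tryptic peptide
COMP = composition_from_sequence(PEPTIDE)


def _obs(intensities, **kw):
    return PeptideObservation(PEPTIDE, np.asarray(intensities, float), **kw)


class TestFitMixture:
    def test_pure_natural_envelope_reports_natural_ria(self):
        nat = envelope(COMP).intensities
        est = fit_mixture(_obs(nat * 1000.0), COMP)
        assert est.ria == pytest.approx(1.1)
        assert est.f_labeled == 0.0
        assert "low-signal" in est.flags

    def test_recovers_half_labeled_half_ria(self):
        mix = mixture_envelope(COMP, 0.50, 0.50).intensities
        est = fit_mixture(_obs(mix * 500.0), COMP)
        assert est.ria == pytest.approx(50.0, abs=0.5)
        assert est.f_labeled == pytest.approx(0.50, abs=0.01)

    def test_tracer_level_ria_exceeds_autotroph_threshold(self):
        mix = mixture_envelope(COMP, 0.99, 1.0).intensities
        est = fit_mixture(_obs(mix * 100.0), COMP)
        assert est.ria > 90.0

    def test_intensity_conservation(self):
        mix = mixture_envelope(COMP, 0.7, 0.3).intensities * 1234.5
        est = fit_mixture(_obs(mix), COMP)
        assert est.i12c >= 0 and est.i13c >= 0
        assert est.i12c + est.i13c == pytest.approx(mix.sum(), rel=1e-6)
        assert est.f_labeled == pytest.approx(est.i13c / (est.i12c + est.i13c))

    def test_zero_carbon_composition_rejected(self):
        with pytest.raises(ValueError, match="carbon"):
            fit_mixture(_obs([1.0, 0.5]), {"H": 2, "O": 1})

    def test_all_zero_envelope_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            _obs([0.0, 0.0, 0.0])

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        mix = mixture_envelope(COMP, 0.4, 0.6).intensities
        noisy = mix * rng.lognormal(0, 0.02, mix.size)
        a = fit_mixture(_obs(noisy), COMP)
        b = fit_mixture(_obs(noisy), COMP)
        assert (a.ria, a.f_labeled, a.objective) == (b.ria, b.f_labeled, b.objective)

    def test_cosine_metric_agrees_on_clean_data(self):
        mix = mixture_envelope(COMP, 0.6, 0.5).intensities
        chi = fit_mixture(_obs(mix), COMP)
        cos = fit_mixture(_obs(mix), COMP, config=FitConfig(metric="cosine"))
        assert cos.ria == pytest.approx(chi.ria, abs=0.5)

    def test_natural_null_median_over_noisy_replicates(self):
        # 200-replicate miniature of the natural-abundance null
        rng = np.random.default_rng(11)
        nat = envelope(COMP).intensities
        rias = []
        for _ in range(200):
            noisy = nat * rng.lognormal(0, 0.02, nat.size) * 1e6
            rias.append(fit_mixture(_obs(noisy), COMP).ria)
        assert np.median(rias) == pytest.approx(1.1, abs=0.2)


class TestParameterRecovery:
    @pytest.mark.parametrize("ria", [0.05, 0.25, 0.50, 0.75, 0.95])
    def test_grid_recovery_under_noise(self, ria):
        """Median errors across f in {0.2, 0.5, 0.8} with 2% noise."""
        rng = np.random.default_rng(int(ria * 1000))
        ria_err, f_err = [], []
        for f in (0.2, 0.5, 0.8):
            for _ in range(6):
                pep = random_tryptic_peptide(rng)
                comp = composition_from_sequence(pep)
                model = mixture_envelope(comp, ria, f).intensities
                noisy = model * rng.lognormal(0, 0.02, model.size) * 1e6
                est = fit_mixture(PeptideObservation(pep, noisy), comp)
                ria_err.append(abs(est.ria - ria * 100.0))
                f_err.append(abs(est.f_labeled - f))
        assert np.median(ria_err) <= 1.0
        assert np.median(f_err) <= 0.05


class TestDeconvolveMonoisotopic:
    def test_pure_unlabeled_envelope(self):
        nat = envelope(COMP).intensities
        est = deconvolve_monoisotopic(_obs(100.0 * nat), COMP)
        assert est.i12c == pytest.approx(100.0 * nat.sum(), rel=1e-9)
        assert est.i13c == pytest.approx(0.0, abs=1e-6)

    def test_forward_constructed_overlap(self):
        nat = envelope(COMP).intensities
        lab = envelope(COMP, 0.95).intensities
        size = max(nat.size, lab.size)
        obs = np.zeros(size)
        obs[: nat.size] += 50.0 * nat
        obs[: lab.size] += 100.0 * lab
        est = deconvolve_monoisotopic(_obs(obs), COMP)
        assert est.i12c == pytest.approx(50.0, rel=0.01)
        assert est.i13c == pytest.approx(100.0, rel=0.01)

    def test_clamp_flagged_not_truncated_silently(self):
        nat = envelope(COMP).intensities
        bad = nat.copy()
        bad[0] *= 5.0  # monoisotopic intensity inconsistent with the total
        est = deconvolve_monoisotopic(_obs(bad), COMP)
        assert "overlap-inconsistent" in est.flags
        assert est.i12c <= bad.sum() * (1 + 1e-9)

    def test_agrees_with_mixture_fit_when_disjoint(self):
        mix = mixture_envelope(COMP, 0.99, 0.6).intensities * 1000.0
        m = fit_mixture(_obs(mix), COMP)
        d = deconvolve_monoisotopic(_obs(mix), COMP, mixture_estimate=m)
        assert d.i12c == pytest.approx(m.i12c, rel=0.02)


class TestSelectMethod:
    def test_disjoint_envelopes_use_mixture_fit(self):
        assert select_method(COMP, 0.99, 1.0) == MIXTURE_FIT

    def test_overlapping_envelopes_use_deconvolution(self):
        assert select_method(COMP, 0.05, 0.5) == MONO_DECONV

    def test_zero_labeled_fraction_uses_mixture_fit(self):
        assert select_method(COMP, 0.05, 0.0) == MIXTURE_FIT

    def test_estimate_records_selected_method(self):
        low = mixture_envelope(COMP, 0.05, 0.5).intensities
        est = estimate(_obs(low * 100.0), COMP)
        assert est.method == MONO_DECONV
        high = mixture_envelope(COMP, 0.99, 0.5).intensities
        est2 = estimate(_obs(high * 100.0), COMP)
        assert est2.method == MIXTURE_FIT


class TestFitPeptideTable:
    def test_table_fit_keeps_metadata_and_conserves_intensity(self):
        obs = simulate_labeled_envelopes(5, 0.99, 1.0, noise_cv=0.0, seed=1)
        obs["genus"] = "Ferrovum"
        obs["timepoint"] = 7.0
        res = fit_peptide_table(obs)
        assert list(res["genus"].unique()) == ["Ferrovum"]
        env_cols = [c for c in obs.columns if c.startswith("i") and c[1:].isdigit()]
        totals = obs[env_cols].sum(axis=1).to_numpy()
        np.testing.assert_allclose(
            (res["I12C"] + res["I13C"]).to_numpy(), totals, rtol=1e-6
        )
        assert (res["ria_percent"] > 90).all()

    def test_missing_envelope_columns_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="envelope"):
            fit_peptide_table(pd.DataFrame({"peptide": ["AAK"]}))
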
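"""Fit scoring, model comparison, and LM / MCMC parameter estimation."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from rotospec import (DEFAULT_MEDIUM, DielectricMaterial, EPSILON_0,
                      FieldConfig, FitResult, LMSpectrumEstimator,
                      MCMCSpectrumEstimator, ParameterSpace, RotationSpectrum,
                      SamplerConfig, SingleShellCell, aic, compare_models,
                      fit_lm, fit_mcmc, fit_pooled, predict_spectrum,
                      reduced_chi2, ssr)


def _spectrum(velocities, frequencies=None, radius=6e-6):
    n = len(velocities)
    f = (np.geomspace(3e3, 10e6, n) if frequencies is None
         else np.asarray(frequencies))
    return RotationSpectrum("c", "x", radius, f, np.asarray(velocities, float))


def _derived(estimates):
    return (estimates["eps_mb"] * EPSILON_0 / estimates["t"],
            estimates["sigma_mb"] / estimates["t"],
            estimates["sigma_cp"])


class TestScoring:
    def test_ssr_examples(self):
        s = _spectrum([1.0, 2.0, 3.0, 4.0, 5.0])
        assert ssr(s, s.velocities) == 0.0
        s3 = _spectrum([0.0, 0.0, 0.0, 1.0, 1.0])
        pred = np.array([-1.0, 1.0, -2.0, 1.0, 1.0])
        assert ssr(s3, pred) == pytest.approx(6.0)
        with pytest.raises(ValueError, match="length"):
            ssr(s, np.zeros(4))

    def test_ssr_monotone_in_points(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=8)
        pred = rng.normal(size=8)
        partial = ssr(_spectrum(u[:7]), pred[:7])
        full = ssr(_spectrum(u), pred)
        assert full >= partial

    def test_aic_exact_arithmetic(self):
        assert aic(1.0, 20, 5) == pytest.approx(10.0)
        assert aic(math.e, 20, 5) == pytest.approx(-10.0)
        assert aic(7.3, 20, 10) - aic(7.3, 20, 5) == pytest.approx(10.0)

    def test_aic_log_base_option(self):
        assert aic(100.0, 10, 3, log_base=10) == pytest.approx(6 - 20)

    def test_aic_rejects_zero_ssr(self):
        with pytest.raises(ValueError, match="noise-free"):
            aic(0.0, 20, 5)

    def test_reduced_chi2(self):
        assert reduced_chi2(15 * 0.3, 20, 5, 0.3) == pytest.approx(1.0)
        assert reduced_chi2(9.0, 20, 5, 0.6) == pytest.approx(
            reduced_chi2(9.0, 20, 5, 0.3) / 2)
        with pytest.raises(ValueError):
            reduced_chi2(1.0, 5, 5, 0.3)


def _fake_fit(aic_value, model="single", n_free=5):
    return FitResult(method="lm", model=model, cell_id="c", cohort="x",
                     radius=6e-6, estimates={}, ssr=1.0, n_points=20,
                     n_free=n_free, aic=aic_value, reduced_chi2=None,
                     converged=True)


class TestModelComparison:
    def test_published_aic_pair_gives_1_percent(self):
        rec = compare_models(_fake_fit(369.0), _fake_fit(378.0, "double", 10))
        assert rec.selected == "single"
        assert rec.relative_probability == pytest.approx(math.exp(-4.5),
                                                         rel=1e-12)
        assert rec.relative_probability == pytest.approx(1.11e-2, rel=1e-2)

    def test_extreme_aic_gap(self):
        rec = compare_models(_fake_fit(181.0), _fake_fit(668.0, "double", 10))
        assert rec.selected == "single"
        assert rec.relative_probability < 1e-100

    def test_tie_prefers_single(self):
        rec = compare_models(_fake_fit(100.0), _fake_fit(100.0, "double", 10))
        assert rec.selected == "single"
        assert rec.tie

    def test_mismatched_spectra_rejected(self):
        other = _fake_fit(5.0, "double", 10)
        other.n_points = 7
        with pytest.raises(ValueError, match="same spectrum"):
            compare_models(_fake_fit(3.0), other)


class TestLMFit:
    def test_noise_free_recovery(self, mose_l_cell, medium, field):
        spec = predict_spectrum(mose_l_cell, medium, field)
        res = fit_lm(spec, seed=1)
        assert res.converged
        assert res.ssr < 1e-12 * spec.peak_speed ** 2
        c_mb, g_mb, s_cp = _derived(res.estimates)
        assert c_mb == pytest.approx(30 * EPSILON_0 / 4e-9, rel=1e-3)
        assert g_mb == pytest.approx(52e-6 / 4e-9, rel=1e-3)
        assert s_cp == pytest.approx(1.0, rel=1e-3)

    def test_estimates_respect_bounds(self, mose_l_cell, medium, field):
        spec = predict_spectrum(mose_l_cell, medium, field)
        rng = np.random.default_rng(5)
        noisy = RotationSpectrum(
            "c", "x", spec.radius, spec.frequencies,
            spec.velocities + rng.normal(0, 0.05 * spec.peak_speed, len(spec)))
        res = fit_lm(noisy, seed=2)
        space = ParameterSpace.single_shell()
        for p in space:
            assert p.lower - 1e-15 <= res.estimates[p.name] <= p.upper + 1e-15

    def test_refit_from_estimate_is_fixed_point(self, mose_l_cell, medium,
                                                field):
        spec = predict_spectrum(mose_l_cell, medium, field)
        first = fit_lm(spec, seed=3)
        names = ParameterSpace.single_shell().free_names
        x0 = [first.estimates[n] for n in names]
        second = fit_lm(spec, seed=3, n_restarts=0, x0=x0)
        for n in names:
            assert second.estimates[n] == pytest.approx(first.estimates[n],
                                                        rel=1e-6)

    def test_all_zero_spectrum_converges_gracefully(self):
        spec = _spectrum(np.zeros(20))
        res = fit_lm(spec, seed=0)
        assert res.converged
        assert np.isfinite(res.ssr)

    def test_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_lm(_spectrum([1.0, 2.0, 3.0]))

    def test_out_of_band_spectrum_rejected(self):
        s = RotationSpectrum("c", "x", 6e-6, np.geomspace(10, 1e6, 10),
                             np.zeros(10))
        with pytest.raises(ValueError, match="band"):
            fit_lm(s)

    def test_sklearn_estimator_contract(self, mose_l_cell, medium, field):
        spec = predict_spectrum(mose_l_cell, medium, field)
        est = LMSpectrumEstimator(radius=spec.radius, seed=1)
        cloned = clone(est)
        assert cloned.get_params()["radius"] == spec.radius
        est.fit(spec.frequencies[:, None], spec.velocities)
        pred = est.predict(spec.frequencies[:, None])
        np.testing.assert_allclose(pred, spec.velocities,
                                   atol=1e-5 * spec.peak_speed)
        assert est.score(spec.frequencies[:, None],
                         spec.velocities) > 0.999

    def test_reduced_chi2_calibrated_on_true_noise(self, mose_l_cell, medium,
                                                   field):
        """With the true noise variance supplied, reduced chi^2 ~ 1."""
        clean = predict_spectrum(mose_l_cell, medium, field)
        sd = 0.05 * clean.peak_speed
        rng = np.random.default_rng(42)
        values = []
        for _ in range(200):
            noisy = RotationSpectrum(
                "c", "x", clean.radius, clean.frequencies,
                clean.velocities + rng.normal(0, sd, len(clean)))
            res = fit_lm(noisy, seed=1, n_restarts=2, n_screen=32)
            values.append(reduced_chi2(res.ssr, res.n_points, res.n_free,
                                       sd ** 2))
        assert 0.8 <= np.mean(values) <= 1.2


class TestMCMCFit:
    budget = SamplerConfig(n_walkers=20, n_temps=3, n_steps=800)

    def test_same_seed_reproduces_samples(self, mose_l_cell, medium, field):
        spec = predict_spectrum(mose_l_cell, medium, field)
        cfg = SamplerConfig(n_walkers=14, n_temps=2, n_steps=100)
        r1 = fit_mcmc(spec, sampler_config=cfg, seed=9)
        r2 = fit_mcmc(spec, sampler_config=cfg, seed=9)
        for name in r1.posterior_samples:
            np.testing.assert_array_equal(r1.posterior_samples[name],
                                          r2.posterior_samples[name])
        assert r1.estimates == r2.estimates

    def test_prior_only_marginals_match_uniform_midpoints(self, mose_l_cell,
                                                          medium, field):
        """Constant likelihood must return the box-uniform prior."""
        spec = predict_spectrum(mose_l_cell, medium, field)
        res = fit_mcmc(spec, sampler_config=SamplerConfig(
            n_walkers=20, n_temps=1, n_steps=1500), seed=4, prior_only=True)
        space = ParameterSpace.single_shell()
        for name in space.free_names:
            p = space[name]
            lo, hi = p.scale_bounds()
            samples = res.posterior_samples[name]
            coord = np.log10(samples) if p.log else samples
            sd = (hi - lo) / np.sqrt(12)
            # ~30k correlated draws; effective sample size is conservative
            se = sd / np.sqrt(100)
            assert abs(coord.mean() - (lo + hi) / 2) < 3 * se

    def test_agrees_with_lm_on_noise_free_data(self, mose_l_cell, medium,
                                               field):
        spec = predict_spectrum(mose_l_cell, medium, field)
        lm = fit_lm(spec, seed=1)
        mc = fit_mcmc(spec, sampler_config=self.budget, seed=6)
        c_lm = lm.estimates["eps_mb"] * EPSILON_0 / lm.estimates["t"]
        c_mc = mc.estimates["eps_mb"] * EPSILON_0 / mc.estimates["t"]
        assert c_mc == pytest.approx(c_lm, rel=0.02)

    def test_posterior_within_bounds(self, mose_l_cell, medium, field):
        spec = predict_spectrum(mose_l_cell, medium, field)
        res = fit_mcmc(spec, sampler_config=SamplerConfig(
            n_walkers=14, n_temps=2, n_steps=200), seed=2)
        space = ParameterSpace.single_shell()
        for name in space.free_names:
            p = space[name]
            samples = res.posterior_samples[name]
            assert samples.min() >= p.lower - 1e-12
            assert samples.max() <= p.upper * (1 + 1e-12)


class TestPooledFit:
    def test_pooled_recovers_shared_parameters(self, medium, field):
        cell_params = dict(membrane=DielectricMaterial(25.0, 40e-6),
                           cytoplasm=DielectricMaterial(60.0, 0.8),
                           membrane_thickness=5e-9)
        spectra = [predict_spectrum(
            SingleShellCell(radius=r, **cell_params), medium, field,
            cell_id=f"c{i}", cohort="pool")
            for i, r in enumerate((5e-6, 6e-6, 8e-6))]
        res = fit_pooled(spectra, seed=0)
        assert res.n_points == 3 * len(field.frequencies)
        c_mb = res.estimates["eps_mb"] * EPSILON_0 / res.estimates["t"]
        assert c_mb == pytest.approx(25 * EPSILON_0 / 5e-9, rel=1e-3)
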
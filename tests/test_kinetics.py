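"""Michaelis-Menten initialization, Bayesian fitting, and N.D. reporting."""

import io

import numpy as np
import pytest

from selenospec import SamplerConfig
from selenospec.kinetics import (
    DEFAULT_S0_GRID,
    KineticsDataset,
    MMHyperParams,
    fit_mm,
    init_mm,
    mm_rate,
    read_kinetics,
    summarize_mm,
    write_kinetics,
)
from selenospec.simulate import KinSimSpec, simulate_kinetics

WT = dict(km=27.8, vmax=22.7)


class TestRate:
    def test_half_saturation_identity(self):
        assert mm_rate(27.8, 27.8, 22.7) == pytest.approx(22.7 / 2, rel=1e-12)

    def test_zero_substrate_gives_zero(self):
        assert mm_rate(0.0, 27.8, 22.7) == 0.0

    def test_wild_type_at_top_concentration(self):
        # 22.7 * 2500 / 2527.8 evaluated independently
        assert mm_rate(2500.0, 27.8, 22.7) == pytest.approx(22.450352084816837, rel=1e-12)

    def test_saturates_at_vmax(self):
        assert mm_rate(1e12, 27.8, 22.7) == pytest.approx(22.7, rel=1e-6)

    @pytest.mark.parametrize("km", [0.0, -1.0])
    def test_nonpositive_km_rejected(self, km):
        with pytest.raises(ValueError):
            mm_rate(10.0, km, 22.7)


class TestInit:
    @pytest.mark.parametrize("km,vmax", [(27.8, 22.7), (169.3, 7.2), (104.4, 8.0)])
    def test_noiseless_recovery_of_reported_parameter_sets(self, km, vmax):
        d = simulate_kinetics(KinSimSpec(km=km, vmax=vmax, noise_sd=0.0, replicates=1))
        init = init_mm(d)
        assert init.mu_K == pytest.approx(km, rel=1e-6)
        assert init.mu_V == pytest.approx(vmax, rel=1e-6)
        assert not init.flat

    def test_noiseless_recovery_random_truths(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            km = float(rng.uniform(1, 2000))
            vmax = float(rng.uniform(0.5, 50))
            d = simulate_kinetics(KinSimSpec(km=km, vmax=vmax, noise_sd=0.0, replicates=1))
            init = init_mm(d)
            assert init.mu_K == pytest.approx(km, rel=1e-6)
            assert init.mu_V == pytest.approx(vmax, rel=1e-6)

    def test_two_informative_points_suffice(self):
        km, vmax = 50.0, 10.0
        d = KineticsDataset(np.array([50.0, 50000.0]),
                            np.array([5.0, mm_rate(50000.0, km, vmax)]))
        init = init_mm(d)
        assert init.mu_K == pytest.approx(km, rel=0.01)
        assert init.mu_V == pytest.approx(vmax, rel=0.01)

    def test_all_zero_rates_fall_back_flagged(self):
        d = KineticsDataset(np.array(DEFAULT_S0_GRID), np.zeros(8))
        init = init_mm(d)
        assert init.flat
        assert init.mu_K > 0 and init.mu_V >= 0


class TestFit:
    def test_recovers_wild_type_truth_within_ten_percent(self):
        d = simulate_kinetics(KinSimSpec(seed=5, **WT))  # noise SD = 5% of V_max
        fit = fit_mm(d, mcmc=SamplerConfig(seed=3))
        assert fit.km_mean == pytest.approx(WT["km"], rel=0.10)
        assert fit.vmax_mean == pytest.approx(WT["vmax"], rel=0.10)
        assert not fit.nd_flag
        assert fit.summary.converged

    def test_low_activity_flags_km_not_determined(self):
        d = simulate_kinetics(KinSimSpec(km=27.8, vmax=0.3, noise_sd=0.1, seed=11))
        fit = fit_mm(d, mcmc=SamplerConfig(seed=4, tune=800, steps=1500,
                                           on_nonconvergence="warn"))
        assert fit.nd_flag
        assert fit.nd_reason is not None
        assert fit.vmax_mean == pytest.approx(0.3, abs=0.15)

    def test_posterior_reproduces_prior_without_rate_data(self):
        # likelihood dropped (missing rates): posterior == prior at (mu_K, mu_V)
        d = KineticsDataset(np.array(DEFAULT_S0_GRID), np.zeros(8))
        h = MMHyperParams(mu_K=80.0, mu_V=5.0, rate_K=2 * 4.0**2, rate_V=2 * 0.25**2)
        fit = fit_mm(d, h, SamplerConfig(seed=9, tune=800, steps=1500,
                                         on_nonconvergence="warn"), prior_only=True)
        # prior is Student-t4 centered at the means with scales 4 and 0.25
        assert abs(fit.km_mean - 80.0) < 1.0
        assert abs(fit.vmax_mean - 5.0) < 0.1

    def test_prior_only_requires_explicit_prior_means(self):
        d = KineticsDataset(np.array(DEFAULT_S0_GRID), np.zeros(8))
        with pytest.raises(ValueError, match="mu_K"):
            fit_mm(d, prior_only=True)

    def test_posterior_spread_monotone_in_noise(self):
        sds = []
        for noise in (0.25, 1.0, 4.0):
            d = simulate_kinetics(KinSimSpec(noise_sd=noise, seed=21, **WT))
            fit = fit_mm(d, mcmc=SamplerConfig(seed=22, tune=800, steps=1500,
                                               on_nonconvergence="warn"))
            sds.append(fit.km_sd)
        assert sds[0] < sds[1] < sds[2]

    def test_positivity_violations_logged(self):
        d = simulate_kinetics(KinSimSpec(seed=5, **WT))
        fit = fit_mm(d, mcmc=SamplerConfig(seed=3, tune=300, steps=300,
                                           on_nonconvergence="warn"))
        assert 0.0 <= fit.positivity_fraction < 1.0

    def test_too_few_distinct_concentrations_rejected(self):
        d = KineticsDataset(np.array([0.0, 10.0, 10.0, 100.0]),
                            np.array([0.0, 5.0, 5.1, 15.0]))
        with pytest.raises(ValueError, match="distinct"):
            fit_mm(d)

    def test_hyperparameters_echoed(self):
        d = simulate_kinetics(KinSimSpec(seed=5, **WT))
        fit = fit_mm(d, mcmc=SamplerConfig(seed=3, tune=300, steps=300,
                                           on_nonconvergence="warn"))
        for key in ("mu_K", "mu_V", "shape_K", "rate_K", "shape_eps", "rate_eps"):
            assert key in fit.hyper


class TestReporting:
    def test_report_row_mean_pm_sd_style(self):
        d = simulate_kinetics(KinSimSpec(seed=5, **WT))
        fit = fit_mm(d, mcmc=SamplerConfig(seed=3, tune=800, steps=1500,
                                           on_nonconvergence="warn"))
        row = summarize_mm(fit, label="WT")
        assert row["enzyme"] == "WT"
        v_str = row["V_max (nmol/min·mg)"]
        mean_part, sd_part = v_str.split(" ± ")
        assert float(mean_part) == pytest.approx(fit.vmax_mean, abs=0.05)
        assert "." in sd_part and len(sd_part.split(".")[1]) == 1  # one decimal

    def test_nd_row_replaces_km(self):
        d = simulate_kinetics(KinSimSpec(km=27.8, vmax=0.3, noise_sd=0.1, seed=11))
        fit = fit_mm(d, mcmc=SamplerConfig(seed=4, tune=500, steps=800,
                                           on_nonconvergence="warn"))
        assert summarize_mm(fit, "L164R-like")["K_M (μM)"] == "N.D."

    def test_csv_roundtrip(self, tmp_path):
        d = simulate_kinetics(KinSimSpec(seed=1, **WT))
        path = tmp_path / "kin.csv"
        write_kinetics(d, path)
        d2 = read_kinetics(path)
        np.testing.assert_allclose(d2.S0, d.S0)
        np.testing.assert_allclose(d2.v0, d.v0)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing column"):
            read_kinetics(io.StringIO("a,b\n1,2\n"))
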
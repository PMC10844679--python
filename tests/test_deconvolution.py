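"""Mixture deconvolution: weight recovery, M0, and group comparison."""

import numpy as np
import pytest

from selenospec import DeconvolutionConfig, SamplerConfig, emg_logpdf, emg_pdf
from selenospec.deconvolution import (
    SpeciationResult,
    aggregate_m0,
    compare_groups,
    deconvolve,
    mixture_logpdf,
)

from conftest import make_mixture_distribution


def make_result(draws, panel=("GSSeSG", "MSA", "selenite", "DMSeO")):
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    return SpeciationResult(
        panel=tuple(panel),
        weight_draws=draws,
        weight_mean={c: float(draws[:, i].mean()) for i, c in enumerate(panel)},
        weight_sd={c: float(draws[:, i].std()) for i, c in enumerate(panel)},
        m0_mean=float("nan"), m0_sd=float("nan"),
    )


class TestMixtureLogpdf:
    def test_degenerate_mixture_equals_component(self, true_library):
        w = np.array([1.0, 0.0, 0.0, 0.0])
        x = np.linspace(8, 20, 50)
        np.testing.assert_allclose(
            mixture_logpdf(x, w, true_library),
            emg_logpdf(x, true_library["GSSeSG"]),
            rtol=1e-12,
        )

    def test_matches_direct_summation(self, true_library):
        w = np.array([0.25, 0.25, 0.25, 0.25])
        x = np.linspace(8, 20, 101)
        direct = np.log(sum(
            wk * emg_pdf(x, p) for wk, p in zip(w, true_library.ordered_params())
        ))
        np.testing.assert_allclose(mixture_logpdf(x, w, true_library), direct, rtol=1e-10)

    def test_well_separated_component_dominates_at_its_apex(self, true_library):
        # at the MSA apex (9 min) every other component is ~zero
        w = np.array([0.25, 0.25, 0.25, 0.25])
        val = mixture_logpdf(9.1, w, true_library)
        expected = np.log(0.25 * emg_pdf(9.1, true_library["MSA"]))
        assert val == pytest.approx(expected, abs=1e-6)

    def test_relabeling_invariance(self, true_library):
        from selenospec.calibration import StandardLibrary

        w = np.array([0.4, 0.3, 0.2, 0.1])
        perm = [2, 0, 3, 1]
        panel_p = tuple(true_library.panel[i] for i in perm)
        lib_p = StandardLibrary(panel_p, {c: true_library[c] for c in panel_p})
        x = np.linspace(8, 20, 20)
        np.testing.assert_allclose(
            mixture_logpdf(x, w, true_library),
            mixture_logpdf(x, w[perm], lib_p),
            rtol=1e-12,
        )

    def test_off_simplex_weights_rejected(self, true_library):
        with pytest.raises(ValueError, match="simplex"):
            mixture_logpdf(10.0, np.array([0.5, 0.5, 0.5, 0.5]), true_library)


class TestDeconvolve:
    def test_pure_component_recovery(self, true_library):
        d = make_mixture_distribution((1.0, 0.0, 0.0, 0.0), seed=13)
        res = deconvolve(d, true_library,
                         DeconvolutionConfig(sampler=SamplerConfig(seed=5)))
        assert res.weight_mean["GSSeSG"] >= 0.95

    def test_every_draw_on_simplex(self, true_library, fast_sampler):
        d = make_mixture_distribution((0.4, 0.3, 0.2, 0.1), seed=7)
        res = deconvolve(d, true_library, DeconvolutionConfig(sampler=fast_sampler))
        assert np.all(res.weight_draws >= 0)
        np.testing.assert_allclose(res.weight_draws.sum(axis=1), 1.0, atol=1e-9)

    def test_responsibilities_sum_to_one_per_bin(self, true_library, fast_sampler):
        d = make_mixture_distribution((0.4, 0.3, 0.2, 0.1), seed=7)
        res = deconvolve(d, true_library, DeconvolutionConfig(sampler=fast_sampler))
        np.testing.assert_allclose(res.responsibilities.sum(axis=1), 1.0, atol=1e-9)

    def test_prior_only_posterior_matches_dirichlet_mean(self, true_library):
        d = make_mixture_distribution((0.25, 0.25, 0.25, 0.25), seed=3)
        res = deconvolve(
            d, true_library,
            DeconvolutionConfig(sampler=SamplerConfig(seed=11)),
            prior_only=True,
        )
        for c in res.panel:
            mcse = 5 * res.weight_sd[c] / np.sqrt(res.summary.ess[min(
                res.summary.ess, key=res.summary.ess.get)])
            assert abs(res.weight_mean[c] - 0.25) < max(mcse, 0.02), c

    def test_recovery_sweep_monotone_and_accurate(self, true_library, fast_sampler):
        truths = [0.1, 0.3, 0.5, 0.7, 0.9]
        means = []
        for i, w1 in enumerate(truths):
            rest = (1 - w1) / 3
            d = make_mixture_distribution((w1, rest, rest, rest), seed=40 + i)
            res = deconvolve(d, true_library, DeconvolutionConfig(sampler=fast_sampler))
            means.append(res.weight_mean["GSSeSG"])
            assert abs(means[-1] - w1) < 0.05
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_coelution_inflates_weight_uncertainty(self, fast_sampler, panel_truths):
        # move selenite's peak toward GSSeSG's: the two weights confound
        from selenospec import EMGParams
        from selenospec.calibration import StandardLibrary

        sds = []
        for sep in (2.4, 0.8, 0.25):
            truths = dict(panel_truths)
            truths["selenite"] = EMGParams(13.6 + sep, 0.10, 5.0)
            lib = StandardLibrary(tuple(truths), truths)
            from selenospec.chromatogram import to_elution_distribution
            from selenospec.simulate import ChromSimSpec, simulate_mixture_chromatogram

            spec = ChromSimSpec(
                components=tuple(truths[c] for c in lib.panel),
                weights=(0.5, 0.0, 0.5, 0.0), total_counts=5000, seed=99,
            )
            d = to_elution_distribution(simulate_mixture_chromatogram(spec))
            res = deconvolve(d, lib, DeconvolutionConfig(sampler=fast_sampler))
            sds.append(res.weight_sd["selenite"])
        assert sds[0] < sds[1] < sds[2]

    def test_alpha_length_mismatch_rejected(self, true_library):
        cfg = DeconvolutionConfig(alpha=(1.0, 1.0, 1.0))
        d = make_mixture_distribution((0.25,) * 4, seed=3)
        with pytest.raises(ValueError, match="panel"):
            deconvolve(d, true_library, cfg)


class TestM0:
    def test_definitional_sum_per_draw(self):
        res = make_result([[0.3, 0.1, 0.2, 0.4]])
        mean, sd = aggregate_m0(res)
        assert mean == pytest.approx(0.5)

    def test_pure_dmseo_gives_zero(self):
        res = make_result([[0.0, 0.0, 0.0, 1.0]] * 3)
        mean, _ = aggregate_m0(res)
        assert mean == 0.0

    def test_mean_equals_sum_of_compound_means(self):
        rng = np.random.default_rng(4)
        draws = rng.dirichlet((1, 1, 1, 1), size=500)
        res = make_result(draws)
        mean, _ = aggregate_m0(res)
        assert mean == pytest.approx(
            res.weight_mean["GSSeSG"] + res.weight_mean["selenite"], abs=1e-12
        )

    def test_missing_compound_rejected(self):
        res = make_result([[0.5, 0.5]], panel=("MSA", "DMSeO"))
        with pytest.raises(ValueError, match="M0"):
            aggregate_m0(res)


class TestCompareGroups:
    def test_identical_groups_null(self):
        res = compare_groups([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_welch_matches_textbook_formula(self):
        a = np.array([10.1, 10.2, 9.9])
        b = np.array([5.0, 5.2, 4.9])
        res = compare_groups(a, b, policy="welch")
        # direct transcription of the Welch statistic
        se = np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        assert res.statistic == pytest.approx((a.mean() - b.mean()) / se, rel=1e-12)
        assert res.pvalue < 0.001
        assert res.test == "welch"

    def test_policies_agree_qualitatively_on_equal_variance_data(self):
        rng = np.random.default_rng(6)
        a = 10 + rng.normal(0, 0.5, 6)
        b = 5 + rng.normal(0, 0.5, 6)
        welch = compare_groups(a, b, policy="welch")
        gated = compare_groups(a, b, policy="f-gated")
        assert gated.test == "student"  # equal variances pass the F gate
        assert (welch.pvalue < 0.05) == (gated.pvalue < 0.05)
        assert gated.variance_test_pvalue is not None

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])
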
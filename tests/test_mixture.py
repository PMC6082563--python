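import math

import numpy as np
import pytest
from scipy.stats import chisquare, poisson

import recckit as rk
from recckit.mixture import fit_fixed_k, fit_parsimonious

from conftest import random_mixture


class TestPoissonPmf:
    def test_zero_events_rate_one(self):
        assert round(rk.poisson_pmf(0, 1.0), 3) == 0.368

    def test_more_than_one_event_rate_one(self):
        p_gt1 = 1.0 - rk.poisson_pmf(0, 1.0) - rk.poisson_pmf(1, 1.0)
        assert round(p_gt1, 3) == 0.264

    def test_degenerate_zero_rate(self):
        assert rk.poisson_pmf(0, 0.0) == 1.0
        assert rk.poisson_pmf(3, 0.0) == 0.0

    def test_matches_scipy(self, rng):
        h = rng.integers(0, 30, 50)
        lam = rng.uniform(0.01, 20.0, 50)
        np.testing.assert_allclose(rk.poisson_pmf(h, lam), poisson.pmf(h, lam), rtol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rk.poisson_pmf(-1, 1.0)
        with pytest.raises(ValueError):
            rk.poisson_pmf(1, -0.5)


class TestLoglik:
    def test_reduces_to_single_poisson(self, rng):
        h = rng.poisson(2.0, 100)
        mix = rk.MixtureDistribution((1.0,), (float(h.mean()),))
        expected = float(np.sum(poisson.logpmf(h, h.mean())))
        assert rk.loglik(rk.CountVector(h), mix) == pytest.approx(expected, rel=1e-12)

    def test_label_invariance(self, rng):
        h = rng.poisson(1.0, 50)
        cv = rk.CountVector(h)
        a = rk.MixtureDistribution((0.3, 0.7), (0.5, 2.0))
        b = rk.MixtureDistribution.from_components((0.7, 0.3), (2.0, 0.5))
        assert rk.loglik(cv, a) == pytest.approx(rk.loglik(cv, b), rel=1e-14)

    def test_direct_summation_oracle(self):
        # counts (0,1,2), q=(.5,.5), lam=(0.5,2): term-by-term evaluation
        cv = rk.CountVector([0, 1, 2])
        mix = rk.MixtureDistribution((0.5, 0.5), (0.5, 2.0))
        expected = sum(
            math.log(
                0.5 * math.exp(-0.5) * 0.5**h / math.factorial(h)
                + 0.5 * math.exp(-2.0) * 2.0**h / math.factorial(h)
            )
            for h in (0, 1, 2)
        )
        assert rk.loglik(cv, mix) == pytest.approx(expected, rel=1e-12)

    def test_zero_density_gives_minus_inf(self):
        mix = rk.MixtureDistribution((1.0,), (0.0,))
        assert rk.loglik(rk.CountVector([0, 1]), mix) == -math.inf

    def test_empty_counts_error(self):
        mix = rk.MixtureDistribution((1.0,), (1.0,))
        with pytest.raises(ValueError):
            rk.loglik(rk.CountVector(np.empty(0, dtype=int)), mix)


class TestGradientFunction:
    def test_equals_one_at_single_component_mle(self, rng):
        h = rng.poisson(3.0, 200)
        cv = rk.CountVector(h)
        mix = rk.MixtureDistribution((1.0,), (float(h.mean()),))
        assert rk.gradient_function(float(h.mean()), cv, mix) == pytest.approx(1.0, abs=1e-12)

    def test_sup_exceeds_one_for_non_optimal_mixture(self):
        # on counts (0,0,5) a single rate at the mean is not the NPMLE
        cv = rk.CountVector([0, 0, 5])
        mix = rk.MixtureDistribution((1.0,), (float(np.mean([0, 0, 5])),))
        grid = np.linspace(0.0, 5.0, 500)
        assert np.max(rk.gradient_function(grid, cv, mix)) > 1.0

    def test_one_at_support_of_converged_fit(self, rng, three_group_mix):
        sim = rk.simulate_counts(three_group_mix, 3000, seed=rng)
        fit = rk.fit_npmle(sim)
        assert fit.converged
        d = rk.gradient_function(np.asarray(fit.mixture.lam), sim, fit.mixture)
        np.testing.assert_allclose(d, 1.0, atol=1e-5)


class TestFitNpmle:
    def test_constant_counts(self):
        fit = rk.fit_npmle(rk.CountVector(np.full(25, 4)))
        assert fit.mixture.k == 1
        assert fit.mixture.lam[0] == pytest.approx(4.0, abs=1e-8)
        assert fit.converged

    def test_all_zero_counts(self):
        fit = rk.fit_npmle(rk.CountVector(np.zeros(10, dtype=int)))
        assert fit.mixture.k == 1
        assert fit.mixture.lam == (0.0,)
        assert fit.loglik == 0.0
        assert fit.converged

    def test_beats_single_poisson_mle(self, rng):
        h = rng.poisson(1.0, 50)
        cv = rk.CountVector(h)
        fit = rk.fit_npmle(cv)
        single = float(np.sum(poisson.logpmf(h, h.mean())))  # closed-form k=1 MLE
        assert fit.loglik >= single - 1e-9

    def test_em_loglik_monotone(self, rng, three_group_mix):
        sim = rk.simulate_counts(three_group_mix, 2000, seed=rng)
        fit = rk.fit_npmle(sim)
        assert fit.em_loglik_traces
        for trace in fit.em_loglik_traces:
            assert np.all(np.diff(trace) >= -1e-9)

    def test_optimality_certificate(self, rng, three_group_mix):
        sim = rk.simulate_counts(three_group_mix, 2000, seed=rng)
        fit = rk.fit_npmle(sim)
        assert fit.converged
        assert fit.max_gradient <= 1.0 + 1e-6
        grid = np.linspace(0.0, float(sim.counts.max()), 1500)
        assert np.max(rk.gradient_function(grid, sim, fit.mixture)) <= 1.0 + 1e-6

    def test_parameter_recovery(self, three_group_mix):
        sim = rk.simulate_counts(three_group_mix, 10_000, seed=1)
        fit = rk.fit_npmle(sim)
        # aggregate fitted components onto the nearest true component
        true_lam = np.asarray(three_group_mix.lam)
        true_q = np.asarray(three_group_mix.q)
        fit_lam = np.asarray(fit.mixture.lam)
        fit_q = np.asarray(fit.mixture.q)
        assign = np.argmin(np.abs(fit_lam[:, None] - true_lam[None, :]), axis=1)
        for j in range(3):
            sel = assign == j
            assert sel.any()
            w = fit_q[sel].sum()
            rate = float(fit_q[sel] @ fit_lam[sel] / w)
            assert abs(w - true_q[j]) < 0.03
            assert abs(rate - true_lam[j]) < 0.15

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rk.fit_npmle(rk.CountVector([0, 1]), grid_size=1)
        with pytest.raises(ValueError):
            rk.fit_npmle(rk.CountVector(np.empty(0, dtype=int)))

    def test_window_years_propagates(self, three_group_mix):
        sim = rk.simulate_counts(three_group_mix, 500, seed=0)
        assert sim.window_years == 2.0
        fit = rk.fit_npmle(sim)
        assert fit.mixture.window_years == 2.0


class TestSimulateCounts:
    def test_zero_rate_all_zero(self):
        mix = rk.MixtureDistribution((1.0,), (0.0,))
        cv = rk.simulate_counts(mix, 50, seed=0)
        assert cv.total == 0

    def test_lln_mean(self):
        mix = rk.MixtureDistribution((1.0,), (5.0,))
        cv = rk.simulate_counts(mix, 100_000, seed=1)
        assert abs(cv.counts.mean() - 5.0) < 3.0 * math.sqrt(5.0 / 100_000)

    def test_reproducible(self, two_group_mix):
        a = rk.simulate_counts(two_group_mix, 100, seed=42)
        b = rk.simulate_counts(two_group_mix, 100, seed=42)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_replicate_mean_matches_mixture_mean(self):
        from recckit.data import URBAN_SEVERE_MIXTURE as mix

        rng = np.random.default_rng(3)
        means = [rk.simulate_counts(mix, 2960, seed=rng).counts.mean() for _ in range(50)]
        # oracle: sum q_j lam_j computed independently
        expected = sum(w * l for w, l in zip(mix.q, mix.lam))
        se = math.sqrt(np.var(means) / len(means))
        assert abs(np.mean(means) - expected) < 4 * se + 1e-9

    def test_poisson_rate_additivity(self, rng):
        # counts from two units with rates a and b, summed, behave as Poisson(a+b)
        a, b = 1.3, 2.1
        s = rng.poisson(a, 20_000) + rng.poisson(b, 20_000)
        edges = np.arange(0, 12)
        observed = np.array([(s == e).sum() for e in edges])
        observed = np.append(observed, (s >= 12).sum())
        probs = poisson.pmf(edges, a + b)
        probs = np.append(probs, 1.0 - probs.sum())
        result = chisquare(observed, probs * s.size)
        assert result.pvalue > 0.01

    def test_time_scaling(self, rng):
        # a k-year window equals rate k*lam
        mix = rk.MixtureDistribution((1.0,), (0.7,))
        two_windows = rk.simulate_counts(mix, 50_000, seed=5).counts + rk.simulate_counts(
            mix, 50_000, seed=6
        ).counts
        scaled = rk.simulate_counts(mix.scaled(2.0), 50_000, seed=7).counts
        assert abs(two_windows.mean() - scaled.mean()) < 4 * math.sqrt(2 * 1.4 / 50_000)


class TestFixedK:
    def test_k1_closed_form(self, rng):
        h = rng.poisson(2.5, 300)
        fit = fit_fixed_k(rk.CountVector(h), 1)
        assert fit.mixture.lam[0] == pytest.approx(h.mean())

    def test_k2_improves_on_k1_for_mixture_data(self, two_group_mix):
        sim = rk.simulate_counts(two_group_mix, 2000, seed=9)
        f1 = fit_fixed_k(sim, 1)
        f2 = fit_fixed_k(sim, 2)
        assert f2.loglik > f1.loglik


class TestBootstrapLrt:
    def test_nboot_floor(self):
        with pytest.raises(ValueError):
            rk.bootstrap_lrt(rk.CountVector([0, 1, 2]), k_null=1, n_boot=10)

    def test_zero_lrt_gives_p_one(self):
        # constant counts: the NPMLE equals the k=1 fit, LRT_obs = 0
        cv = rk.CountVector(np.full(30, 2))
        report = rk.bootstrap_lrt(cv, k_null=1, n_boot=19, seed=0)
        assert report.statistic == pytest.approx(0.0, abs=1e-9)
        assert report.p_value == 1.0

    def test_power_on_separated_mixture(self, two_group_mix):
        sim = rk.simulate_counts(two_group_mix, 2000, seed=3)
        report = rk.bootstrap_lrt(sim, k_null=1, n_boot=19, seed=4)
        assert report.p_value <= 0.05

    def test_null_calibration(self):
        # data from the null: rejection at 5% should be rare
        mix = rk.MixtureDistribution((1.0,), (1.0,))
        rejections = 0
        for s in range(20):
            sim = rk.simulate_counts(mix, 200, seed=100 + s)
            report = rk.bootstrap_lrt(sim, k_null=1, n_boot=19, seed=s)
            rejections += report.p_value <= 0.05
        assert rejections <= 4  # binomial(20, 0.05) upper tail


class TestFitParsimonious:
    def test_keeps_separated_mixture(self, two_group_mix):
        sim = rk.simulate_counts(two_group_mix, 2000, seed=8)
        fit = fit_parsimonious(sim, seed=8)
        assert fit.mixture.k >= 2

    def test_collapses_to_single_rate_under_null(self):
        mix = rk.MixtureDistribution((1.0,), (0.2,))
        sim = rk.simulate_counts(mix, 242, seed=13)
        fit = fit_parsimonious(sim, seed=13)
        assert fit.mixture.k == 1
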
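"""EZ closed form, chi-square and K-S distances, and the fitting harness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wienerfit import (DMParams, Dataset, OptimizerSettings, build_super_curve,
                       cs_df, cs_statistic, draw_starting_values, ez_estimate,
                       ez_forward_moments, ez_moments, fit, ks_critical,
                       ks_statistic, prob_lower, sample_trials)
from wienerfit.estimators import EZMoments, _model_super_cdf


class TestEZMoments:
    def test_pc_is_upper_proportion(self):
        rng = np.random.default_rng(0)
        responses = (np.arange(100) >= 28).astype(int)  # 28 % lower
        d = Dataset(responses=responses, rts=rng.uniform(0.3, 1.0, 100))
        assert ez_moments(d).pc == pytest.approx(0.72)

    def test_upper_scope_conditional_moments(self):
        d = Dataset(responses=np.array([1, 1, 0]),
                    rts=np.array([0.5, 0.7, 2.0]))
        m = ez_moments(d, scope="upper")
        assert m.mrt == pytest.approx(0.6)
        assert m.vrt == pytest.approx(0.02)

    def test_all_upper_is_degenerate_under_upper_scope(self):
        d = Dataset(responses=np.ones(10, dtype=int),
                    rts=np.linspace(0.4, 0.9, 10))
        assert ez_moments(d, scope="upper").pc == 1.0
        assert not ez_moments(d, scope="all").degenerate


class TestEZInversion:
    def test_forward_inverse_round_trip_exact(self, theta_unbiased):
        m = ez_forward_moments(theta_unbiased)
        back = ez_estimate(m)
        assert back.a == pytest.approx(theta_unbiased.a, abs=1e-8)
        assert back.ter == pytest.approx(theta_unbiased.ter, abs=1e-8)
        assert back.v == pytest.approx(theta_unbiased.v, abs=1e-8)
        assert back.z_rel == 0.5

    def test_forward_closed_matches_quadrature(self, theta_unbiased):
        mc = ez_forward_moments(theta_unbiased, "closed")
        mq = ez_forward_moments(theta_unbiased, "quadrature")
        assert mc.mrt == pytest.approx(mq.mrt, abs=1e-6)
        assert mc.vrt == pytest.approx(mq.vrt, abs=1e-6)
        assert mc.pc == pytest.approx(mq.pc, abs=1e-9)

    def test_zero_drift_limit_gives_half(self):
        assert ez_forward_moments(DMParams(1, 0.5, 0.2, 0)).pc == pytest.approx(0.5)

    def test_pc_monotone_in_drift(self):
        pcs = [ez_forward_moments(DMParams(1, 0.5, 0.2, v)).pc
               for v in (-1, -0.5, 0, 0.5, 1)]
        assert np.all(np.diff(pcs) > 0)

    def test_pc_half_edge_rule_gives_finite_output(self):
        m = EZMoments(mrt=0.6, vrt=0.04, pc=0.5, n=100)
        est = ez_estimate(m)
        assert np.isfinite(est.a) and np.isfinite(est.v) and np.isfinite(est.ter)

    def test_population_negative_ter_at_biased_cell(self):
        """With a large boundary, a start far from the middle and zero
        drift, even the population moments invert to a negative
        non-decision time — the invalid-estimate pathway."""
        from scipy.integrate import quad
        from wienerfit.wiener import fpt_density
        th = DMParams(2, 0.2, 0.1, 0.0)
        pc = 1 - prob_lower(th)
        mix = lambda t: (fpt_density(t + th.ter, "upper", th)
                         + fpt_density(t + th.ter, "lower", th))
        m1, _ = quad(lambda t: t * mix(t), 0, 100, limit=400)
        m2, _ = quad(lambda t: t * t * mix(t), 0, 100, limit=400)
        est = ez_estimate(EZMoments(mrt=th.ter + m1, vrt=m2 - m1 ** 2,
                                    pc=pc, n=10 ** 6))
        assert est.ter < 0


class TestCSStatistic:
    def test_zero_when_observed_equals_expected(self, data_400, theta_unbiased):
        # fit the statistic's own expected counts as observations
        from wienerfit.estimators import build_cs_binning, _expected_counts
        b = build_cs_binning(data_400)
        b.obs_lower = _expected_counts(b.edges_lower, "lower", theta_unbiased, data_400.n)
        b.obs_upper = _expected_counts(b.edges_upper, "upper", theta_unbiased, data_400.n)
        assert cs_statistic(data_400, theta_unbiased, binning=b) == pytest.approx(0, abs=1e-9)

    def test_toy_arithmetic(self):
        obs = np.array([12, 8, 10, 10, 10, 10], dtype=float)
        exp = np.full(6, 10.0)
        assert np.sum((obs - exp) ** 2 / exp) == pytest.approx(0.8)

    def test_order_invariance(self, data_400, theta_unbiased):
        perm = np.random.default_rng(0).permutation(data_400.n)
        shuffled = Dataset(responses=data_400.responses[perm],
                          rts=data_400.rts[perm])
        assert cs_statistic(shuffled, theta_unbiased) == pytest.approx(
            cs_statistic(data_400, theta_unbiased))

    def test_statistic_mean_near_bins_minus_one_at_truth(self, theta_unbiased):
        """Unminimized CS at the generating parameters is ~ chi-square with
        B - 1 = 11 degrees of freedom."""
        vals = [cs_statistic(sample_trials(theta_unbiased, 800, seed=2000 + s),
                             theta_unbiased) for s in range(60)]
        assert np.mean(vals) == pytest.approx(11.0, abs=2.0)

    def test_sparse_boundary_collapses_to_single_bin(self):
        responses = np.concatenate([np.zeros(3), np.ones(97)]).astype(int)
        rng = np.random.default_rng(1)
        d = Dataset(responses=responses, rts=rng.uniform(0.3, 1.5, 100))
        from wienerfit.estimators import build_cs_binning
        b = build_cs_binning(d)
        assert b.obs_lower.size == 1 and b.obs_lower[0] == 3
        assert b.obs_upper.size == 6

    @pytest.mark.parametrize("C,B,P,expected", [(1, 12, 4, 7), (2, 12, 4, 18)])
    def test_df_formula(self, C, B, P, expected):
        assert cs_df(C, B, P) == expected

    def test_df_nonpositive_warns(self):
        with pytest.warns(UserWarning):
            assert cs_df(1, 5, 4) == 0


class TestKSStatistic:
    def test_junction_height_is_lower_proportion(self):
        rng = np.random.default_rng(0)
        responses = (np.arange(100) >= 28).astype(int)
        d = Dataset(responses=responses, rts=rng.uniform(0.3, 1.0, 100))
        assert build_super_curve(d).junction == pytest.approx(0.28)

    def test_model_super_curve_junction(self, theta_unbiased):
        eps = 1e-9
        left = _model_super_cdf(np.array([-eps]), theta_unbiased)[0]
        assert left == pytest.approx(prob_lower(theta_unbiased), abs=1e-6)

    def test_sup_at_jumps_equals_dense_grid(self, data_100, theta_unbiased):
        stat = ks_statistic(data_100, theta_unbiased)
        grid = np.linspace(-data_100.rts.max() - 1, data_100.rts.max() + 1, 40001)
        signed = np.where(data_100.upper_mask, data_100.rts, -data_100.rts)
        emp = np.searchsorted(np.sort(signed), grid, side="right") / data_100.n
        brute = np.max(np.abs(emp - _model_super_cdf(grid, theta_unbiased)))
        assert stat == pytest.approx(brute, abs=1e-3)
        assert stat >= brute - 1e-12  # jump evaluation can only be sharper

    def test_statistic_shrinks_with_n(self, theta_unbiased):
        stats = [ks_statistic(sample_trials(theta_unbiased, n, seed=5),
                              theta_unbiased) for n in (50, 400, 3200)]
        assert stats[0] > stats[2]

    @pytest.mark.parametrize("alpha,expected", [
        (0.05, 1.35810), (0.5, 0.83255), (1 - 1e-9, 0.58871)])
    def test_critical_value(self, alpha, expected):
        assert ks_critical(alpha) == pytest.approx(expected, abs=1e-4)

    def test_critical_value_domain(self):
        for bad in (0.0, 1.0, -1, 2):
            with pytest.raises(ValueError):
                ks_critical(bad)


class TestStartingValues:
    def test_ranges_and_fixed_ter(self):
        rng = np.random.default_rng(0)
        draws = [draw_starting_values(rng) for _ in range(2000)]
        assert all(s.ter0 == 0.001 for s in draws)
        a0 = np.array([s.a0 for s in draws])
        assert a0.min() >= 0.2 and a0.max() <= 0.8
        # seeded reproducibility
        rng2 = np.random.default_rng(0)
        again = draw_starting_values(rng2)
        assert (again.a0, again.z0, again.v0) == (draws[0].a0, draws[0].z0, draws[0].v0)


class TestFit:
    def test_ml_recovers_truth_on_average(self, theta_unbiased):
        """Mean ML estimate over replicate datasets is within 3 Monte-Carlo
        standard errors of the truth at n = 400."""
        ests = []
        for s in range(25):
            d = sample_trials(theta_unbiased, 400, seed=3000 + s)
            r = fit(d, "ml", seed=s)
            ests.append(r.params_hat.as_tuple())
        ests = np.array(ests)
        truth = np.array(theta_unbiased.as_tuple())
        se = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
        assert np.all(np.abs(ests.mean(axis=0) - truth) < 3.5 * se + 0.02)

    def test_optimizers_agree(self, data_400):
        results = {}
        for alg in ("nelder-mead", "bfgs", "newton"):
            r = fit(data_400, "ml", OptimizerSettings(algorithm=alg), seed=1)
            assert r.converged
            results[alg] = np.array(r.params_hat.as_tuple())
        for alg in ("bfgs", "newton"):
            np.testing.assert_allclose(results[alg], results["nelder-mead"],
                                       atol=1e-3)

    def test_iteration_cap_respected(self, data_100):
        r = fit(data_100, "ml", seed=0)
        assert r.iterations <= 5000

    def test_same_seed_and_start_reproduce(self, data_100):
        r1 = fit(data_100, "ks", seed=4)
        r2 = fit(data_100, "ks", seed=4)
        assert r1.params_hat.as_tuple() == r2.params_hat.as_tuple()

    def test_failure_returns_unconverged_result(self):
        # two-trial dataset: optimizers may do poorly but must not raise
        d = Dataset(responses=np.array([1, 0]), rts=np.array([0.4, 0.5]))
        r = fit(d, "ml", seed=0)
        assert r is not None and hasattr(r, "converged")
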
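"""Partial sums, Monte-Carlo null, Cauchy combination, split-level test."""

import numpy as np
import pytest
from scipy import stats

from ps5 import (ScenarioConfig, cauchy_combine, draw_null_contributions,
                 generate, marginal_pvalues, mcp_select, partial_sums,
                 ps_pvalues, remove_marginal_exposure, split_samples,
                 test_split as run_split_test)


class TestPartialSums:
    def test_forced_arithmetic(self):
        ps, order = partial_sums([3.0, 1.0, 2.0], gamma=2.0)
        np.testing.assert_allclose(ps, [9.0, 13.0, 14.0])
        np.testing.assert_array_equal(order, [0, 2, 1])

    def test_single_entry(self):
        ps, _ = partial_sums([0.4], gamma=2.0)
        assert ps[0] == pytest.approx(0.16)

    def test_l1_identity(self, rng):
        t = rng.uniform(0, 5, 17)
        ps, _ = partial_sums(t, gamma=1.0)
        assert ps[-1] == pytest.approx(t.sum())

    def test_nondecreasing(self, rng):
        t = rng.uniform(0, 2, 30)
        ps, _ = partial_sums(t, gamma=2.5)
        assert np.all(np.diff(ps) >= 0)

    def test_ties_broken_by_original_index(self):
        _, order = partial_sums([1.0, 2.0, 2.0], gamma=1.0)
        np.testing.assert_array_equal(order, [1, 2, 0])

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            partial_sums([], 2.0)
        with pytest.raises(ValueError):
            partial_sums([-1.0], 2.0)
        with pytest.raises(ValueError):
            partial_sums([1.0], 0.0)


class TestNullDraws:
    def test_degenerate_covariance_gives_zero(self):
        draws = draw_null_contributions([1.0, -2.0], [0.5, 0.5],
                                        np.zeros((2, 2)), np.zeros((2, 2)),
                                        B=200, seed=3)
        np.testing.assert_allclose(draws, 0.0, atol=1e-14)

    def test_product_normal_oracle(self):
        """q=1 at zero estimates: draws follow the symmetric product-normal."""
        draws = draw_null_contributions([0.0], [0.0], [[1.0]], [[1.0]],
                                        B=40_000, seed=5).ravel()
        rng = np.random.default_rng(99)
        oracle = np.abs(rng.standard_normal(40_000) * rng.standard_normal(40_000))
        ks = stats.ks_2samp(draws, oracle).statistic
        assert ks < 0.02

    def test_seed_determinism(self):
        kw = dict(alpha_X=[0.3], beta_M=[1.0], cov_alpha=[[0.01]],
                  cov_beta=[[0.02]], B=50, seed=11)
        np.testing.assert_array_equal(draw_null_contributions(**kw),
                                      draw_null_contributions(**kw))

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError):
            draw_null_contributions([0.0, 0.0], [0.0, 0.0],
                                    [[1.0, 2.0], [2.0, 1.0]], np.eye(2),
                                    B=100, seed=0)


class TestPSPvalues:
    def test_floor_when_observed_dominates(self):
        null = np.full((99, 2), 0.01)
        p = ps_pvalues([5.0, 9.0], null, gamma=2.0)
        np.testing.assert_allclose(p, 1.0 / 100.0)

    def test_one_when_observed_is_zero(self):
        null = np.abs(np.random.default_rng(1).standard_normal((50, 2))) + 0.1
        p = ps_pvalues([0.0, 0.0], null, gamma=2.0)
        np.testing.assert_allclose(p, 1.0)

    def test_monotone_in_signal(self, rng):
        """Scaling all observed statistics up never increases any p_k."""
        t = rng.uniform(0.1, 1.0, 6)
        null = np.abs(rng.standard_normal((400, 6)))
        ps1, _ = partial_sums(t, 2.0)
        ps2, _ = partial_sums(3.0 * t, 2.0)
        p1 = ps_pvalues(ps1, null, 2.0)
        p2 = ps_pvalues(ps2, null, 2.0)
        assert np.all(p2 <= p1)


class TestCauchyCombine:
    def test_median_inputs(self):
        stat, p = cauchy_combine([0.5, 0.5, 0.5])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5)

    def test_identity_for_single_p(self):
        for pv in (0.1, 0.01, 0.73):
            _, p = cauchy_combine([pv])
            assert p == pytest.approx(pv, rel=1e-10)

    def test_direct_transcendental_evaluation(self):
        stat, _ = cauchy_combine([0.01, 0.5, 0.9])
        expected = (np.tan(0.49 * np.pi) + 0.0 - np.tan(0.4 * np.pi)) / 3.0
        assert stat == pytest.approx(expected, rel=1e-12)

    def test_cauchy_closure_under_uniform_inputs(self):
        """Mean-tangent of independent uniforms is standard Cauchy."""
        rng = np.random.default_rng(7)
        stats_ = [cauchy_combine(rng.uniform(size=5))[0] for _ in range(10_000)]
        ks = stats.kstest(stats_, "cauchy").statistic
        assert ks < 0.02

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cauchy_combine([])


class TestMarginalPvalues:
    def test_floor_and_ceiling(self):
        null = np.abs(np.random.default_rng(0).standard_normal((199, 2))) + 0.1
        p = marginal_pvalues([99.0, 0.0], null)
        assert p[0] == pytest.approx(1.0 / 200.0)
        assert p[1] == pytest.approx(1.0)


@pytest.fixture(scope="module")
def strong_split():
    cfg = ScenarioConfig(kind="alternative", n=400, p=30, s=2,
                         alpha_strength=1.0, seed=55)
    data, truth = generate(cfg)
    plan = split_samples(data.n_samples, seed=2)
    resid = remove_marginal_exposure(data)
    sel = mcp_select(resid, data.covariates, plan.d1_rows, seed=2,
                     cv_folds=4, n_lambda=30)
    return data, plan, sel


class TestSplitLevel:
    def test_strong_signal_is_detected(self, strong_split):
        data, plan, sel = strong_split
        fit = run_split_test(data, plan, sel, gamma=2.0, B=500, seed=3)
        assert fit.p_global < 0.01
        assert fit.ie > 0.5

    def test_bit_identical_reruns(self, strong_split):
        data, plan, sel = strong_split
        a = run_split_test(data, plan, sel, gamma=2.0, B=300, seed=3)
        b = run_split_test(data, plan, sel, gamma=2.0, B=300, seed=3)
        assert a.p_global == b.p_global
        np.testing.assert_array_equal(a.ps.p_k, b.ps.p_k)
        np.testing.assert_array_equal(a.effect.contributions,
                                      b.effect.contributions)

    def test_cancelation_still_detected(self):
        """Contributions +c and -c null the summed IE but not the PS test."""
        rng = np.random.default_rng(31)
        n = 600
        x = rng.standard_normal(n)
        m1 = 1.0 * x + 0.2 * rng.standard_normal(n)
        m2 = -1.0 * x + 0.2 * rng.standard_normal(n)
        m3 = rng.standard_normal(n)
        y = 1.0 * m1 + 1.0 * m2 + 0.05 * rng.standard_normal(n)
        from ps5 import MediationDataset
        data = MediationDataset(exposure=x, outcome=y,
                                mediators=np.column_stack([m1, m2, m3]))
        plan = split_samples(n, seed=8)
        resid = remove_marginal_exposure(data)
        sel = mcp_select(resid, None, plan.d1_rows, seed=8, cv_folds=4,
                         n_lambda=25)
        fit = run_split_test(data, plan, sel, gamma=2.0, B=500, seed=9)
        assert abs(fit.ie) < 0.3          # global IE cancels
        assert fit.p_global < 0.01        # but the PS test rejects

    def test_gamma3_at_least_as_powerful_in_sparse_regime(self):
        """Heavier gamma emphasizes the sparse single-signal alternative."""
        cfg = ScenarioConfig(kind="alternative", n=300, p=60, s=1,
                             alpha_strength=0.35, seed=77)
        rejections = {1.0: 0, 3.0: 0}
        from ps5 import replicate_stream
        for i, (data, truth) in enumerate(replicate_stream(cfg, 25)):
            plan = split_samples(data.n_samples, seed=i)
            resid = remove_marginal_exposure(data)
            sel = mcp_select(resid, None, plan.d1_rows, seed=i, cv_folds=4,
                             n_lambda=25)
            for gamma in rejections:
                fit = run_split_test(data, plan, sel, gamma=gamma, B=300, seed=i)
                rejections[gamma] += fit.p_global < 0.05
        assert rejections[3.0] >= rejections[1.0]
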
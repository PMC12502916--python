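"""Unit tests for the structural regressions and effect summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ps5 import (EmptySelectionError, MediationDataset, SingularDesignError,
                 effect_summary, estimate_total_effect, fit_mediator_models,
                 fit_outcome_model, neutralization_ratio)

from conftest import make_dataset


def exact_outcome_dataset(n=40):
    """Noiseless outcome: Y = 1 + 2 X + 3 M1 with independent M1."""
    rng = np.random.default_rng(7)
    x = rng.standard_normal(n)
    m1 = rng.standard_normal(n)
    m2 = rng.standard_normal(n)
    y = 1.0 + 2.0 * x + 3.0 * m1
    return MediationDataset(exposure=x, outcome=y,
                            mediators=np.column_stack([m1, m2]))


def exact_mediator_dataset(n=40):
    """Noiseless mediator equation: M1 = 4 X."""
    rng = np.random.default_rng(8)
    x = rng.standard_normal(n)
    m1 = 4.0 * x
    m2 = rng.standard_normal(n)
    return MediationDataset(exposure=x, outcome=rng.standard_normal(n),
                            mediators=np.column_stack([m1, m2]))


class TestOutcomeModel:
    def test_noiseless_exact_recovery(self):
        data = exact_outcome_dataset()
        fit = fit_outcome_model(data, ["M1"], np.arange(data.n_samples))
        assert fit.beta_X == pytest.approx(2.0, abs=1e-10)
        assert fit.beta_M[0] == pytest.approx(3.0, abs=1e-10)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-18)

    def test_matches_normal_equations_oracle(self):
        data = make_dataset(n=50, p=3, seed=3, covariates=2)
        rows = np.arange(50)
        fit = fit_outcome_model(data, ["M1", "M2", "M3"], rows)
        # independent dense normal-equations solve
        design = np.column_stack([np.ones(50), data.covariates,
                                  data.exposure, data.mediators])
        coef = np.linalg.solve(design.T @ design, design.T @ data.outcome)
        np.testing.assert_allclose(fit.beta_C, coef[:3], atol=1e-8)
        assert fit.beta_X == pytest.approx(coef[3], abs=1e-8)
        np.testing.assert_allclose(fit.beta_M, coef[4:], atol=1e-8)
        resid = data.outcome - design @ coef
        sigma2 = resid @ resid / (50 - design.shape[1])
        assert fit.sigma2 == pytest.approx(sigma2, rel=1e-8)
        cov = sigma2 * np.linalg.inv(design.T @ design)[4:, 4:]
        np.testing.assert_allclose(fit.cov_beta_M, cov, rtol=1e-7)

    def test_permutation_invariance(self):
        data = make_dataset(n=45, p=2, seed=5)
        rows = np.arange(45)
        fit1 = fit_outcome_model(data, ["M1", "M2"], rows)
        fit2 = fit_outcome_model(data, ["M1", "M2"],
                                 np.random.default_rng(0).permutation(45))
        np.testing.assert_allclose(fit1.beta_M, fit2.beta_M, atol=1e-10)
        assert fit1.beta_X == pytest.approx(fit2.beta_X, abs=1e-10)
        assert fit1.sigma2 == pytest.approx(fit2.sigma2, rel=1e-10)

    def test_singular_design_names_columns(self):
        data = make_dataset(n=40, p=2, seed=1)
        dup = MediationDataset(
            exposure=data.exposure, outcome=data.outcome,
            mediators=np.column_stack([data.mediators[:, 0],
                                       data.mediators[:, 0]]),
            mediator_names=("M1", "M1dup"))
        with pytest.raises(SingularDesignError) as err:
            fit_outcome_model(dup, ["M1", "M1dup"], np.arange(40))
        assert "M1dup" in str(err.value)

    def test_empty_selection_is_signaled(self):
        data = make_dataset()
        with pytest.raises(EmptySelectionError):
            fit_outcome_model(data, [], np.arange(data.n_samples))


class TestMediatorModels:
    def test_noiseless_exact(self):
        data = exact_mediator_dataset()
        fit = fit_mediator_models(data, ["M1"], np.arange(data.n_samples))
        assert fit.alpha_X[0] == pytest.approx(4.0, abs=1e-10)
        assert fit.sigma_M[0, 0] == pytest.approx(0.0, abs=1e-18)

    def test_matches_per_equation_ols_oracle(self):
        data = make_dataset(n=200, p=2, seed=11)
        rows = np.arange(200)
        fit = fit_mediator_models(data, ["M1", "M2"], rows)
        design = np.column_stack([np.ones(200), data.exposure])
        gram_inv = np.linalg.inv(design.T @ design)
        for j in range(2):
            coef = gram_inv @ design.T @ data.mediators[:, j]
            assert fit.alpha_X[j] == pytest.approx(coef[1], abs=1e-8)
        # independently drawn mediator noises -> near-zero cross-covariance
        assert abs(fit.cov_alpha_X[0, 1]) < 0.2 * np.sqrt(
            fit.cov_alpha_X[0, 0] * fit.cov_alpha_X[1, 1]) + 1e-3

    def test_cov_alpha_is_scaled_sigma_m(self):
        data = make_dataset(n=80, p=3, seed=2, covariates=1)
        fit = fit_mediator_models(data, ["M1", "M2", "M3"], np.arange(80))
        ratio = fit.cov_alpha_X / fit.sigma_M
        assert np.allclose(ratio, ratio.flat[0])

    def test_row_duplication_leaves_alpha_unchanged(self):
        data = make_dataset(n=50, p=2, seed=9)
        rows = np.arange(50)
        doubled = np.concatenate([rows, rows])
        f1 = fit_mediator_models(data, ["M1", "M2"], rows)
        f2 = fit_mediator_models(data, ["M1", "M2"], doubled)
        np.testing.assert_allclose(f1.alpha_X, f2.alpha_X, atol=1e-10)


class TestEffectSummary:
    def _fits(self, alpha, beta):
        data = make_dataset(n=80, p=len(alpha), seed=13)
        names = data.mediator_names
        out = fit_outcome_model(data, names, np.arange(80))
        med = fit_mediator_models(data, names, np.arange(80))
        out = out.__class__(beta_M=np.asarray(beta, float), beta_X=out.beta_X,
                            beta_C=out.beta_C, cov_beta_M=out.cov_beta_M,
                            sigma2=out.sigma2, n_used=out.n_used,
                            mediator_names=out.mediator_names)
        med = med.__class__(alpha_X=np.asarray(alpha, float),
                            alpha_C=med.alpha_C, cov_alpha_X=med.cov_alpha_X,
                            sigma_M=med.sigma_M, n_used=med.n_used,
                            mediator_names=med.mediator_names)
        return out, med

    def test_forced_contributions(self):
        out, med = self._fits([1.0, 1.0], [0.5, 0.5])
        summ = effect_summary(out, med, te=2.0)
        assert summ.nie == pytest.approx(1.0)
        assert summ.gm_pct == pytest.approx(0.5)
        assert summ.nr == pytest.approx(0.0)

    def test_perfect_cancelation(self):
        out, med = self._fits([1.0, 1.0], [0.5, -0.5])
        summ = effect_summary(out, med, te=2.0)
        assert summ.nie == pytest.approx(0.0, abs=1e-12)
        assert summ.nr == pytest.approx(1.0)

    def test_nie_is_dot_product(self, rng):
        alpha = rng.standard_normal(10)
        beta = rng.standard_normal(10)
        out, med = self._fits(alpha, beta)
        summ = effect_summary(out, med, te=1.0)
        assert summ.nie == pytest.approx(float(alpha @ beta), abs=1e-12)
        assert summ.nie == pytest.approx(summ.contributions.sum(), abs=1e-12)

    def test_zero_te_flags_gm_undefined(self):
        out, med = self._fits([1.0], [1.0])
        with pytest.warns(RuntimeWarning):
            summ = effect_summary(out, med, te=0.0)
        assert np.isnan(summ.gm_pct)


class TestNeutralizationRatio:
    @pytest.mark.parametrize("contrib, expected", [
        ((1.0, 2.0, 3.0), 0.0),
        ((2.0, -1.0), 2.0 / 3.0),
        ((-2.0, 1.0), 2.0 / 3.0),   # sign-flip convention
        ((0.0, 0.0), 0.0),
        ((1.0, -1.0), 1.0),
    ])
    def test_known_values(self, contrib, expected):
        assert neutralization_ratio(contrib) == pytest.approx(expected)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=20),
           st.floats(0.01, 100).flatmap(
               lambda c: st.sampled_from([c, -c])))
    def test_bounds_and_scale_invariance(self, contrib, c):
        v = np.asarray(contrib)
        nr = neutralization_ratio(v)
        assert 0.0 <= nr <= 1.0 + 1e-12
        assert neutralization_ratio(c * v) == pytest.approx(nr, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            neutralization_ratio([])


class TestTotalEffect:
    def test_noiseless(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        data = MediationDataset(exposure=x, outcome=3.0 * x,
                                mediators=rng.standard_normal((30, 1)))
        assert estimate_total_effect(data) == pytest.approx(3.0, abs=1e-10)

    def test_te_equals_nde_plus_nie(self, small_alternative):
        """Under the linear model TE ~ NDE + NIE within sampling error."""
        data, truth = small_alternative
        te = estimate_total_effect(data)
        expected = truth.beta_X + truth.true_ie
        # ~3 SEs: Var(Y|X) ~ p + 1 = 41 here, so SE(TE) ~ sqrt(41/240) ~ 0.41
        assert abs(te - expected) < 1.25

    def test_decomposition_on_full_selection(self, small_alternative):
        data, truth = small_alternative
        names = data.mediator_names
        rows = np.arange(data.n_samples)
        out = fit_outcome_model(data, names, rows)
        med = fit_mediator_models(data, names, rows)
        summ = effect_summary(out, med, estimate_total_effect(data))
        assert summ.nie + summ.nde == pytest.approx(summ.te, abs=1e-8)
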
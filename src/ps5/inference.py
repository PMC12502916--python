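"""Step 2: partial-sum statistics and Monte-Carlo inference on D2.

With the q mediators selected on D1, maximum-likelihood estimates are
formed on data the selection never saw: the outcome regression (giving
beta_M and its covariance) is fitted on D2, while the mediator regressions
(giving alpha_X and its covariance) are fitted on the full dataset, since
they involve no selection.  The per-mediator contribution statistics
T_j = |alpha_Xj * beta_Mj| are sorted in decreasing order and accumulated
into partial sums PS_k = sum_{j<=k} T_(j)^gamma, k = 1..q; the family over
k adapts to unknown signal sparsity (PS_1 targets a single strong signal,
PS_q dense ones).  Each PS_k gets a Monte-Carlo p-value from a plug-in
normal approximation to the joint law of (alpha_hat, beta_hat) —
block-diagonal, since the outcome and mediator noises are independent —
and the dependent p-values p_1..p_q are combined with the Cauchy
combination test, whose null distribution is standard Cauchy even under
dependence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import MediationDataset
from .linmod import (EffectSummary, effect_summary, estimate_total_effect,
                     fit_mediator_models, fit_outcome_model)
from .selection import SelectionResult, SplitPlan

__all__ = [
    "PSTestResult",
    "SplitFit",
    "partial_sums",
    "draw_null_contributions",
    "ps_pvalues",
    "cauchy_combine",
    "marginal_pvalues",
    "test_split",
]

_P_CLIP = 1e-15


@dataclass(frozen=True)
class PSTestResult:
    """Everything the partial-sum test produced for one split."""

    t_obs: np.ndarray         # (q,) T_j = |alpha_Xj beta_Mj|
    order: np.ndarray         # permutation sorting t_obs descending
    ps_obs: np.ndarray        # (q,) observed partial sums
    p_k: np.ndarray           # (q,) Monte-Carlo p-values, floor 1/(B+1)
    cauchy_stat: float
    p_global: float
    p_marginal: np.ndarray    # (q,) per-mediator marginal p-values
    gamma: float
    B: int
    seed: int
    mediator_names: tuple


@dataclass(frozen=True)
class SplitFit:
    """Everything estimated within one sample split."""

    plan: SplitPlan
    selection: SelectionResult
    effect: EffectSummary
    ps: PSTestResult            # None when no mediators were selected

    @property
    def p_global(self) -> float:
        return 1.0 if self.ps is None else self.ps.p_global

    @property
    def ie(self) -> float:
        return self.effect.nie


def partial_sums(t, gamma: float):
    """Cumulative sums of the gamma-th powers of t sorted descending.

    Ties are broken by original index (ascending); the first entry is the
    single largest statistic.  Returns (partial sums, sort order).
    """
    t = np.asarray(t, dtype=float).ravel()
    if t.size == 0:
        raise ValueError("empty statistic vector")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if np.any(t < 0):
        raise ValueError("statistics must be non-negative")
    order = np.lexsort((np.arange(t.size), -t))
    return np.cumsum(t[order] ** gamma), order


def _psd_sqrt(cov, name):
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    cov = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(cov)
    scale = max(np.abs(w).max(), 1.0)
    if w.min() < -1e-8 * scale:
        raise ValueError(f"{name} covariance is not positive semi-definite")
    return v * np.sqrt(np.clip(w, 0.0, None))


def draw_null_contributions(alpha_X, beta_M, cov_alpha, cov_beta, B: int,
                            seed: int):
    """Centered Monte-Carlo contribution statistics under the plug-in normal.

    Draws (alpha^(b), beta^(b)) from independent q-variate normals centered
    at the estimates, forms the products alpha_j^(b) beta_j^(b), and returns
    the B x q matrix of centered absolute statistics
    ``T_j^(b)(0) = |prod - mean_b(prod)|``.
    """
    if B < 1:
        raise ValueError("B must be positive")
    alpha_X = np.asarray(alpha_X, dtype=float).ravel()
    beta_M = np.asarray(beta_M, dtype=float).ravel()
    la = _psd_sqrt(cov_alpha, "alpha")
    lb = _psd_sqrt(cov_beta, "beta")
    q = alpha_X.size
    rng = np.random.default_rng(int(seed))
    a_draws = alpha_X + rng.standard_normal((B, q)) @ la.T
    b_draws = beta_M + rng.standard_normal((B, q)) @ lb.T
    prod = a_draws * b_draws
    return np.abs(prod - prod.mean(axis=0))


def ps_pvalues(ps_obs, null_contribs, gamma: float):
    """Add-one Monte-Carlo p-values for each partial-sum statistic.

    The null partial sums are computed from the centered draws exactly as
    for the observed data; ``p_k = (1 + #{b : PS_k^(b) >= PS_k}) / (B+1)``,
    so a large observed partial sum yields a small p-value with floor
    1/(B+1).
    """
    ps_obs = np.asarray(ps_obs, dtype=float).ravel()
    null_contribs = np.asarray(null_contribs, dtype=float)
    if null_contribs.shape[1] != ps_obs.size:
        raise ValueError("shape mismatch between observed and null statistics")
    null_sorted = -np.sort(-null_contribs, axis=1)
    ps_null = np.cumsum(null_sorted ** gamma, axis=1)
    exceed = (ps_null >= ps_obs[None, :]).sum(axis=0)
    b = null_contribs.shape[0]
    return (1.0 + exceed) / (b + 1.0)


def cauchy_combine(p):
    """Cauchy combination of possibly dependent p-values.

    Returns (T, p_global) with ``T = mean(tan((0.5 - p) pi))`` and
    ``p_global`` its upper-tail standard-Cauchy probability.  Inputs are
    clipped into [1e-15, 1 - 1e-15]; for a single p-value the combination
    is the identity.
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    stat = float(np.mean(np.tan((0.5 - p) * np.pi)))
    return stat, float(stats.cauchy.sf(stat))


def marginal_pvalues(t_obs, null_contribs):
    """Per-mediator add-one Monte-Carlo p-values from the shared null draws."""
    t_obs = np.asarray(t_obs, dtype=float).ravel()
    null_contribs = np.asarray(null_contribs, dtype=float)
    if null_contribs.shape[1] != t_obs.size:
        raise ValueError("shape mismatch between observed and null statistics")
    exceed = (null_contribs >= t_obs[None, :]).sum(axis=0)
    b = null_contribs.shape[0]
    return (1.0 + exceed) / (b + 1.0)


def test_split(data: MediationDataset, plan: SplitPlan,
               selection: SelectionResult, gamma: float = 2.0,
               B: int = 10_000, seed: int = 0, te=None) -> SplitFit:
    """Assemble the full partial-sum test for one split.

    beta_M and its covariance come from D2 (mandatory, selection used D1);
    alpha_X and its covariance come from the full dataset, which involves
    no selection.  An empty selection is not an error: the split reports
    IE = 0 and p_global = 1.
    """
    if te is None:
        te = estimate_total_effect(data)
    all_rows = np.arange(data.n_samples)

    if selection.n_selected == 0:
        out = fit_outcome_no_mediators(data, plan.d2_rows)
        effect = EffectSummary(nie=0.0, nde=out, te=float(te),
                               gm_pct=(0.0 if abs(te) > 1e-10 else float("nan")),
                               nr=0.0, contributions=np.empty(0),
                               mediator_names=())
        return SplitFit(plan=plan, selection=selection, effect=effect, ps=None)

    outcome_fit = fit_outcome_model(data, selection.selected, plan.d2_rows)
    mediator_fit = fit_mediator_models(data, selection.selected, all_rows)
    effect = effect_summary(outcome_fit, mediator_fit, te)

    t_obs = np.abs(effect.contributions)
    ps_obs, order = partial_sums(t_obs, gamma)
    null = draw_null_contributions(mediator_fit.alpha_X, outcome_fit.beta_M,
                                   mediator_fit.cov_alpha_X,
                                   outcome_fit.cov_beta_M, B, seed)
    p_k = ps_pvalues(ps_obs, null, gamma)
    stat, p_global = cauchy_combine(p_k)
    p_marg = marginal_pvalues(t_obs, null)
    ps = PSTestResult(t_obs=t_obs, order=order, ps_obs=ps_obs, p_k=p_k,
                      cauchy_stat=stat, p_global=p_global, p_marginal=p_marg,
                      gamma=float(gamma), B=int(B), seed=int(seed),
                      mediator_names=tuple(selection.selected))
    return SplitFit(plan=plan, selection=selection, effect=effect, ps=ps)


def fit_outcome_no_mediators(data: MediationDataset, rows) -> float:
    """Exposure coefficient of Y ~ 1 + C + X on the given rows (NDE when q=0)."""
    return estimate_total_effect(data, rows)
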
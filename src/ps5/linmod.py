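"""Structural linear mediation model and causal-effect summaries.

The observed-data model is a pair of Gaussian linear regressions

    Y = C' beta_C + X beta_X + M' beta_M + eps_Y,     eps_Y ~ N(0, sigma^2)
    M = alpha_C C + X alpha_X + eps_M,                eps_M ~ N_p(0, Sigma_M)

with eps_Y independent of eps_M and no exposure-mediator interaction.
Under the standard no-unmeasured-confounding and cross-world assumptions
the natural direct effect (NDE) is beta_X, the natural indirect effect
(NIE) is sum_j alpha_Xj beta_Mj, and the total effect decomposes as
TE = NDE + NIE.  The global mediation percentage GM% = NIE / TE and the
neutralization ratio NR quantify, respectively, how much of the total
effect flows through the mediators and how much absolute mediation mass is
canceled between positive and negative per-mediator contributions.

Every regression includes an intercept; residual (co)variances use the
unbiased denominator (n minus the number of fitted parameters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import MediationDataset
from .exceptions import EmptySelectionError, SingularDesignError

__all__ = [
    "OutcomeFit",
    "MediatorFit",
    "EffectSummary",
    "fit_outcome_model",
    "fit_mediator_models",
    "effect_summary",
    "neutralization_ratio",
    "estimate_total_effect",
]

#: |TE| below this is treated as "no total effect": GM% is undefined (NaN).
TE_TOLERANCE = 1e-10


@dataclass(frozen=True)
class OutcomeFit:
    """Least-squares fit of the outcome regression on [1, C, X, M_selected]."""

    beta_M: np.ndarray          # (q,) mediator coefficients
    beta_X: float               # exposure coefficient (the NDE)
    beta_C: np.ndarray          # (l+1,) intercept + covariate coefficients
    cov_beta_M: np.ndarray      # (q, q) covariance of beta_M
    sigma2: float               # residual variance, unbiased denominator
    n_used: int
    mediator_names: tuple


@dataclass(frozen=True)
class MediatorFit:
    """Stacked OLS fits of each selected mediator on the shared design [1, C, X].

    Because every mediator equation shares one design matrix, the sampling
    covariance of the stacked exposure coefficients factorizes as
    ``cov_alpha_X = g_xx * sigma_M`` where ``g_xx`` is the exposure diagonal
    entry of the design's inverse Gram matrix.
    """

    alpha_X: np.ndarray         # (q,)
    alpha_C: np.ndarray         # (q, l+1) intercept + covariate coefficients
    cov_alpha_X: np.ndarray     # (q, q)
    sigma_M: np.ndarray         # (q, q) residual cross-covariance
    n_used: int
    mediator_names: tuple


@dataclass(frozen=True)
class EffectSummary:
    """Causal-effect summaries derived from a pair of fitted regressions."""

    nie: float
    nde: float
    te: float
    gm_pct: float               # NIE / TE, NaN when |TE| ~ 0
    nr: float                   # neutralization ratio in [0, 1]
    contributions: np.ndarray   # (q,) alpha_Xj * beta_Mj
    mediator_names: tuple


def _design_with_intercept(data: MediationDataset, rows, extra=None, extra_names=()):
    """Assemble [1, C, X(, extra)] over the requested rows with column names."""
    rows = np.asarray(rows, dtype=int)
    parts = [np.ones((rows.size, 1)), data.covariates[rows]]
    names = ["(intercept)", *data.covariate_names]
    parts.append(data.exposure[rows, None])
    names.append("(exposure)")
    if extra is not None:
        parts.append(extra)
        names.extend(extra_names)
    return np.hstack(parts), names


def _solve_ols(design, response, names):
    """QR-based exact least squares with an explicit rank check.

    Returns (coef, rss, inverse Gram).  A vanishing pivot in R flags the
    offending column(s) by name.
    """
    n, k = design.shape
    q_mat, r_mat = np.linalg.qr(design)
    diag = np.abs(np.diag(r_mat))
    tol = n * np.finfo(float).eps * (diag.max() if k else 0.0)
    bad = np.where(diag <= tol)[0]
    if bad.size:
        raise SingularDesignError([names[i] for i in bad])
    coef = np.linalg.solve(r_mat, q_mat.T @ response)
    resid = response - design @ coef
    rss = resid.T @ resid if resid.ndim > 1 else float(resid @ resid)
    r_inv = np.linalg.solve(r_mat, np.eye(k))
    gram_inv = r_inv @ r_inv.T
    return coef, rss, gram_inv, resid


def fit_outcome_model(data: MediationDataset, selected, rows) -> OutcomeFit:
    """Fit Y ~ 1 + C + X + M_selected by exact least squares on ``rows``.

    ``cov_beta_M`` is sigma2 times the mediator block of the inverse Gram
    matrix; ``sigma2`` uses the unbiased denominator n - (q + l + 2).
    """
    selected = list(selected)
    if len(selected) == 0:
        raise EmptySelectionError("outcome model requires a non-empty mediator set")
    rows = np.asarray(rows, dtype=int)
    cols = data.mediator_index(selected)
    q = cols.size
    l = data.n_covariates
    n = rows.size
    if n <= q + l + 2:
        raise ValueError(
            f"too few rows (n={n}) for q={q} mediators and l={l} covariates"
        )
    design, names = _design_with_intercept(
        data, rows, extra=data.mediators[np.ix_(rows, cols)],
        extra_names=[str(s) for s in selected],
    )
    y = data.outcome[rows]
    coef, rss, gram_inv, _ = _solve_ols(design, y, names)
    k = design.shape[1]
    dof = n - k
    sigma2 = float(rss / dof) if dof > 0 else 0.0
    m_slice = slice(l + 2, k)
    return OutcomeFit(
        beta_M=coef[m_slice].copy(),
        beta_X=float(coef[l + 1]),
        beta_C=coef[: l + 1].copy(),
        cov_beta_M=sigma2 * gram_inv[m_slice, m_slice],
        sigma2=sigma2,
        n_used=n,
        mediator_names=tuple(map(str, selected)),
    )


def fit_mediator_models(data: MediationDataset, selected, rows) -> MediatorFit:
    """Fit every selected mediator on the shared design [1, C, X] over ``rows``."""
    selected = list(selected)
    if len(selected) == 0:
        raise EmptySelectionError("mediator model requires a non-empty mediator set")
    rows = np.asarray(rows, dtype=int)
    cols = data.mediator_index(selected)
    l = data.n_covariates
    n = rows.size
    if n <= l + 2:
        raise ValueError(f"too few rows (n={n}) for l={l} covariates")
    design, names = _design_with_intercept(data, rows)
    m_block = data.mediators[np.ix_(rows, cols)]
    coef, _, gram_inv, resid = _solve_ols(design, m_block, names)
    dof = n - (l + 2)
    sigma_m = (resid.T @ resid) / dof
    sigma_m = np.atleast_2d(sigma_m)
    g_xx = gram_inv[l + 1, l + 1]
    return MediatorFit(
        alpha_X=coef[l + 1].copy(),
        alpha_C=coef[: l + 1].T.copy(),
        cov_alpha_X=g_xx * sigma_m,
        sigma_M=sigma_m,
        n_used=n,
        mediator_names=tuple(map(str, selected)),
    )


def neutralization_ratio(contributions) -> float:
    """Fraction of absolute mediation mass canceled between opposite signs.

    NR = 1 - IE / (|IE+| + |IE-|) with IE = sum of contributions and
    IE+/IE- the positive/negative parts.  The ratio is defined for the
    dominant direction: when IE < 0 the contributions are sign-flipped
    first so NR always lies in [0, 1].  An all-zero vector gives 0.
    """
    c = np.asarray(contributions, dtype=float).ravel()
    if c.size == 0:
        raise ValueError("contributions must be non-empty")
    ie = c.sum()
    if ie < 0:
        c = -c
        ie = -ie
    denom = np.abs(c).sum()
    if denom == 0.0:
        return 0.0
    return float(1.0 - ie / denom)


def effect_summary(outcome_fit: OutcomeFit, mediator_fit: MediatorFit,
                   te: float) -> EffectSummary:
    """Combine the two fitted regressions into NIE/NDE/TE/GM%/NR.

    ``te`` is the externally estimated total effect; GM% = NIE/TE is flagged
    undefined (NaN, with a warning) when |TE| is below tolerance.
    """
    if outcome_fit.mediator_names != mediator_fit.mediator_names:
        raise ValueError("fits must share the same selected mediators and order")
    contributions = mediator_fit.alpha_X * outcome_fit.beta_M
    nie = float(contributions.sum())
    if abs(te) < TE_TOLERANCE:
        warnings.warn("total effect is ~0; GM% is undefined", RuntimeWarning,
                      stacklevel=2)
        gm = float("nan")
    else:
        gm = nie / te
    return EffectSummary(
        nie=nie,
        nde=outcome_fit.beta_X,
        te=float(te),
        gm_pct=gm,
        nr=neutralization_ratio(contributions),
        contributions=contributions,
        mediator_names=outcome_fit.mediator_names,
    )


def estimate_total_effect(data: MediationDataset, rows=None) -> float:
    """Exposure coefficient of Y ~ 1 + C + X over ``rows`` (default: all).

    The total effect involves no mediator selection, so it is estimated
    once from the requested rows (by default the full dataset).
    """
    if rows is None:
        rows = np.arange(data.n_samples)
    rows = np.asarray(rows, dtype=int)
    design, names = _design_with_intercept(data, rows)
    coef, _, _, _ = _solve_ols(design, data.outcome[rows], names)
    return float(coef[data.n_covariates + 1])
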
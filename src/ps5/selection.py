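"""Step 1: sample splitting, marginal exposure removal, MCP mediator selection.

The sample is partitioned into two halves: D1 drives variable selection and
D2 is reserved untouched for inference, so that post-selection p-values
remain valid.  Before selection, the marginal exposure effect is removed
from the outcome and from every mediator (simple regressions on [1, X] over
all N rows — these involve no selection), which stabilizes selection when
exposure effects on the mediators induce collinearity.  Selection itself
minimizes a penalized least-squares criterion on D1 with the minimax
concave penalty on the mediator coefficients; covariates are unpenalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from sklearn.model_selection import KFold

from ._mcp import mcp_path
from .data import MediationDataset
from .exceptions import DataValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "ResidualizedData",
    "SelectionResult",
    "split_samples",
    "remove_marginal_exposure",
    "mcp_select",
]


@dataclass(frozen=True)
class SplitPlan:
    """A deterministic half/half partition of 0..n-1.

    Odd n places the extra row in D2, the inference half.
    """

    d1_rows: np.ndarray
    d2_rows: np.ndarray
    seed: int


@dataclass(frozen=True)
class ResidualizedData:
    """Outcome and mediators with marginal exposure effects removed.

    ``mu_Y = Y - X beta_hat`` and ``mu_M[:, j] = M_j - X alpha_hat_j`` from
    per-column simple regressions on [1, X]; every residual column is
    orthogonal to the intercept and to X.
    """

    mu_Y: np.ndarray
    mu_M: np.ndarray
    mediator_ids: tuple


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of MCP selection on D1."""

    selected: tuple                 # mediator ids, original column order
    selected_idx: np.ndarray        # positions into the mediator matrix
    lambda_chosen: float
    lambda_path: np.ndarray
    criterion_values: np.ndarray    # CV prediction error per lambda (NaN if no CV)
    mcp_a: float
    coefficients: np.ndarray        # original-scale beta_M at lambda_chosen, length p

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def split_samples(n: int, seed: int) -> SplitPlan:
    """Uniformly random half/half partition, deterministic given (n, seed)."""
    if n < 8:
        raise ValueError("need at least 8 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n1 = n // 2
    return SplitPlan(
        d1_rows=np.sort(perm[:n1]),
        d2_rows=np.sort(perm[n1:]),
        seed=int(seed),
    )


def remove_marginal_exposure(data: MediationDataset) -> ResidualizedData:
    """Residualize Y and every mediator on [1, X] over all N rows.

    Covariates deliberately do not enter these marginal regressions; they
    enter the penalized selection criterion directly.
    """
    x = data.exposure
    if np.var(x) <= 0.0:
        raise DataValidationError("constant exposure")
    design = np.column_stack([np.ones_like(x), x])
    gram = design.T @ design
    rhs = design.T @ np.column_stack([data.outcome, data.mediators])
    coef = np.linalg.solve(gram, rhs)
    resid = np.column_stack([data.outcome, data.mediators]) - design @ coef
    return ResidualizedData(
        mu_Y=resid[:, 0].copy(),
        mu_M=resid[:, 1:].copy(),
        mediator_ids=data.mediator_names,
    )


def _project_out(basis, response, basis_new=None, response_new=None):
    """Residualize ``response`` on ``basis`` (exact OLS); optionally apply the
    same fitted projection to held-out rows."""
    coef, *_ = np.linalg.lstsq(basis, response, rcond=None)
    resid = response - basis @ coef
    if basis_new is None:
        return resid
    return resid, response_new - basis_new @ coef


def _standardize(m):
    """Center columns and scale to x'x/n = 1; zero-variance columns become 0."""
    center = m.mean(axis=0)
    centered = m - center
    scale = np.sqrt((centered ** 2).mean(axis=0))
    ok = scale > 0
    out = np.zeros_like(centered)
    out[:, ok] = centered[:, ok] / scale[ok]
    return out, center, scale, ok


def _prepare(mu_y, mu_m, covariates):
    """Project out [1, C], then standardize the mediator block."""
    n = mu_y.shape[0]
    basis = np.column_stack([np.ones(n), covariates]) if covariates is not None \
        and covariates.size else np.ones((n, 1))
    joint = _project_out(basis, np.column_stack([mu_y, mu_m]))
    y_p = joint[:, 0]
    m_p = joint[:, 1:]
    m_std, center, scale, ok = _standardize(m_p)
    return y_p, m_std, scale, ok, basis


def _lambda_ladder(m_std, y_p, n_lambda, min_ratio):
    n = y_p.shape[0]
    lam_max = np.max(np.abs(m_std.T @ y_p) / n)
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambda)


def _ebic(rss, sizes, n, p, gamma_ebic=1.0):
    """Extended BIC along a path of fitted models."""
    sizes = np.asarray(sizes)
    log_comb = gammaln(p + 1) - gammaln(sizes + 1) - gammaln(p - sizes + 1)
    return (n * np.log(np.maximum(rss, 1e-300) / n)
            + sizes * np.log(n) + 2.0 * gamma_ebic * log_comb)


def mcp_select(residuals: ResidualizedData, covariates, rows, *,
               lambda_path=None, mcp_a: float = 3.0, seed: int = 0,
               criterion: str = "ebic", cv_folds: int = 10,
               n_lambda: int = 100, lambda_min_ratio: float = 0.01,
               max_selected=None, tol: float = 1e-7,
               max_sweeps: int = 10_000) -> SelectionResult:
    """MCP-penalized outcome regression on D1 with a tuned penalty level.

    Mediators are standardized to unit variance within the fitting rows
    before penalization and coefficients are returned on the original
    scale; covariates (plus an intercept) are unpenalized and projected
    out exactly.  The path is a log-spaced ladder of ``n_lambda`` values
    from lambda_max (empty model) down to
    ``lambda_min_ratio * lambda_max``.

    The penalty level is chosen by the ``criterion``:

    - ``"ebic"`` (default): minimize the extended BIC (gamma = 1) over the
      path, restricted to supports that keep at least three observations
      per fitted parameter.  The restriction matters: at very small
      penalties the non-convex path behaves like greedy best-subset search
      and nearly interpolates the response with ~n/2 adaptively chosen
      columns, which defeats any purely likelihood-based criterion.
    - ``"cv"``: ``cv_folds``-fold cross-validation minimizing squared
      prediction error of the per-fold penalized fits.  With weak,
      spread-out signals the fold-level paths reach their own solution
      regimes at fold-specific penalty levels, which makes the pooled
      error curve favor under-selection; kept as an option for dense,
      well-separated problems.

    Ties go to the sparser (larger) penalty.  ``max_selected`` caps the
    model size by moving up the ladder to the smallest lambda satisfying
    the cap.
    """
    if criterion not in ("ebic", "cv"):
        raise ValueError("criterion must be 'ebic' or 'cv'")
    rows = np.asarray(rows, dtype=int)
    mu_y = residuals.mu_Y[rows]
    mu_m = residuals.mu_M[rows]
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] == residuals.mu_Y.shape[0]:
            cov = cov[rows]

    y_p, m_std, scale, ok, _ = _prepare(mu_y, mu_m, cov)
    n, p = m_std.shape

    if lambda_path is None:
        lambdas = _lambda_ladder(m_std, y_p, n_lambda, lambda_min_ratio)
    else:
        lambdas = np.sort(np.asarray(lambda_path, dtype=float))[::-1]
        if lambdas.size == 0:
            raise ValueError("empty lambda path")

    dof_cap = max(1, n // 3)                    # >= 3 observations/parameter
    stop_size = dof_cap if criterion == "ebic" else None
    betas, n_done = mcp_path(m_std, y_p, lambdas, a=mcp_a, tol=tol,
                             max_sweeps=max_sweeps, stop_size=stop_size,
                             return_n_done=True)
    # points past an early stop are never candidates; drop them
    lambdas = lambdas[:n_done]
    betas = betas[:n_done]
    sizes = (betas != 0).sum(axis=1)

    cv_err = np.full(lambdas.size, np.nan)
    if criterion == "ebic" and lambdas.size > 1:
        rss = ((y_p[:, None] - m_std @ betas.T) ** 2).sum(axis=0)
        crit = _ebic(rss, sizes, n, int(ok.sum()))
        crit[sizes > dof_cap] = np.inf
        cv_err = crit
        best = int(np.argmin(crit))
    elif criterion == "cv" and lambdas.size > 1 and cv_folds and cv_folds >= 2:
        cv_err = np.zeros(lambdas.size)
        kf = KFold(n_splits=min(cv_folds, n), shuffle=True, random_state=int(seed))
        for tr, va in kf.split(np.arange(n)):
            basis_tr = np.column_stack([np.ones(tr.size), cov[tr]]) if cov is not None \
                and cov.size else np.ones((tr.size, 1))
            basis_va = np.column_stack([np.ones(va.size), cov[va]]) if cov is not None \
                and cov.size else np.ones((va.size, 1))
            joint_tr, joint_va = _project_out(
                basis_tr, np.column_stack([mu_y[tr], mu_m[tr]]),
                basis_va, np.column_stack([mu_y[va], mu_m[va]]))
            ytr, mtr = joint_tr[:, 0], joint_tr[:, 1:]
            yva, mva = joint_va[:, 0], joint_va[:, 1:]
            m_tr_std, center_tr, scale_tr, ok_tr = _standardize(mtr)
            fold_betas = mcp_path(m_tr_std, ytr, lambdas, a=mcp_a, tol=tol,
                                  max_sweeps=max_sweeps)
            mva_std = np.zeros_like(mva)
            mva_std[:, ok_tr] = (mva[:, ok_tr] - center_tr[ok_tr]) / scale_tr[ok_tr]
            pred = mva_std @ fold_betas.T                 # (n_va, n_lambda)
            cv_err += ((yva[:, None] - pred) ** 2).sum(axis=0)
        best = int(np.argmin(cv_err))  # argmin takes the first (largest lambda) tie
    else:
        best = lambdas.size - 1

    if max_selected is not None and sizes[best] > max_selected:
        feasible = np.where(sizes[: best + 1] <= max_selected)[0]
        new_best = int(feasible[-1]) if feasible.size else 0
        logger.warning(
            "selected model size %d exceeds cap %d; moving lambda up the "
            "path (%g -> %g)", sizes[best], max_selected, lambdas[best],
            lambdas[new_best])
        best = new_best

    beta_std = betas[best]
    coef = np.zeros(p)
    coef[ok] = beta_std[ok] / scale[ok]
    sel_idx = np.where(coef != 0)[0]
    return SelectionResult(
        selected=tuple(residuals.mediator_ids[j] for j in sel_idx),
        selected_idx=sel_idx,
        lambda_chosen=float(lambdas[best]),
        lambda_path=lambdas,
        criterion_values=cv_err,
        mcp_a=float(mcp_a),
        coefficients=coef,
    )
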
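"""Synthetic data with the statistical structure of the simulation study.

Datasets are drawn from the structural model

    M = X alpha_X' + eps_M,   eps_M ~ MVN(0, Sigma_M)
    Y = beta_X X + M beta_M + eps_Y,   eps_Y ~ N(0, 1)

with X ~ N(0, 1) (a PRS-like continuous exposure) or Bernoulli(0.5), no
covariates, and unit noise variances.  Sigma_M is either AR1
(Sigma[a,b] = rho^|a-b|) or a pairwise block structure (disjoint
consecutive pairs at correlation rho, emulating strongly correlated
mediators that share a mediation direction).

Five coefficient regimes are supported.  The four null regimes all have
sum_j alpha_Xj beta_Mj = 0 exactly:

- complete_null:    alpha_X = beta_M = 0
- dense_null:       alpha_X ~ U(1,3), beta_M = 0
- sparse_null:      alpha_X = 0, beta_M(1..50) ~ U(1,3), rest 0
- disjunctive_null: alpha_X(1..50) = 0, alpha_X(51..p) ~ U(1,3),
                    beta_M(1..50) ~ U(1,3), rest 0
- alternative:      beta_M(1..50) = beta_value, alpha_X(1..s) =
                    alpha_strength (the s active mediators)

U(1,3) coefficients are redrawn independently per replicate.  The direct
effect defaults to beta_X = 0.5 so the total effect differs from the
indirect effect and GM% is non-trivial.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .data import MediationDataset

__all__ = ["ScenarioConfig", "GroundTruth", "make_covariance", "generate",
           "replicate_stream"]

KINDS = ("complete_null", "dense_null", "sparse_null", "disjunctive_null",
         "alternative")
N_BETA_ACTIVE = 50   # the leading block carrying beta_M effects


@dataclass(frozen=True)
class ScenarioConfig:
    """Declarative description of one simulation regime."""

    kind: str = "alternative"
    n: int = 500
    p: int = 1000
    corr: str = "ar1"             # "ar1" or "block"
    rho: float = 0.0
    pair_size: int = 2
    s: int = 5                    # |S|: alpha-active count among the first 50
    alpha_strength: float = 0.2
    beta_value: float = 1.0
    beta_X: float = 0.5
    exposure: str = "gaussian"    # "gaussian" or "binary"
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.n < 2 or self.p < 2:
            raise ValueError("n and p must be at least 2")
        if self.kind == "alternative" and not (
                0 <= self.s <= min(N_BETA_ACTIVE, self.p)):
            raise ValueError("s must satisfy 0 <= s <= min(50, p)")
        if self.exposure not in ("gaussian", "binary"):
            raise ValueError("exposure must be 'gaussian' or 'binary'")

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """The generating coefficients and the implied mediation truth."""

    alpha_X: np.ndarray
    beta_M: np.ndarray
    beta_X: float
    true_ie: float
    active_set: tuple   # mediator ids with alpha_Xj * beta_Mj != 0

    def to_json(self) -> str:
        return json.dumps({
            "beta_X": self.beta_X,
            "true_ie": self.true_ie,
            "active_set": list(self.active_set),
            "alpha_X": self.alpha_X.tolist(),
            "beta_M": self.beta_M.tolist(),
        })


def make_covariance(p: int, corr: str = "ar1", rho: float = 0.0,
                    pair_size: int = 2, n_paired: int = None) -> np.ndarray:
    """Mediator-noise covariance matrix.

    ``ar1`` gives Sigma[a,b] = rho^|a-b|; ``block`` gives the identity with
    disjoint consecutive groups of ``pair_size`` (over the leading
    ``n_paired`` columns, default all) set to off-diagonal rho.  Both are
    symmetric positive definite for rho in [0, 1).
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    if corr == "ar1":
        idx = np.arange(p)
        return rho ** np.abs(idx[:, None] - idx[None, :])
    if corr == "block":
        sigma = np.eye(p)
        stop = p if n_paired is None else min(n_paired, p)
        for start in range(0, stop - pair_size + 1, pair_size):
            block = slice(start, start + pair_size)
            sigma[block, block] = rho
            sigma[block, block][np.diag_indices(pair_size)] = 1.0
        return sigma
    raise ValueError(f"unknown correlation spec {corr!r}")


def _draw_noise(rng, n, p, corr, rho, pair_size, n_paired):
    """Sample eps_M ~ MVN(0, Sigma_M) using the structure directly."""
    z = rng.standard_normal((n, p))
    if rho == 0.0:
        return z
    if corr == "ar1":
        e = np.empty_like(z)
        e[:, 0] = z[:, 0]
        c = np.sqrt(1.0 - rho * rho)
        for j in range(1, p):
            e[:, j] = rho * e[:, j - 1] + c * z[:, j]
        return e
    if corr == "block":
        if pair_size != 2:
            chol = np.linalg.cholesky(
                make_covariance(p, corr, rho, pair_size, n_paired))
            return z @ chol.T
        e = z.copy()
        stop = p if n_paired is None else min(n_paired, p)
        c = np.sqrt(1.0 - rho * rho)
        for start in range(0, stop - 1, 2):
            e[:, start + 1] = rho * z[:, start] + c * z[:, start + 1]
        return e
    raise ValueError(f"unknown correlation spec {corr!r}")


def _coefficients(rng, config: ScenarioConfig):
    p = config.p
    alpha = np.zeros(p)
    beta = np.zeros(p)
    nb = min(N_BETA_ACTIVE, p)
    kind = config.kind
    if kind == "complete_null":
        pass
    elif kind == "dense_null":
        alpha[:] = rng.uniform(1.0, 3.0, size=p)
    elif kind == "sparse_null":
        beta[:nb] = rng.uniform(1.0, 3.0, size=nb)
    elif kind == "disjunctive_null":
        alpha[nb:] = rng.uniform(1.0, 3.0, size=p - nb)
        beta[:nb] = rng.uniform(1.0, 3.0, size=nb)
    elif kind == "alternative":
        beta[:nb] = config.beta_value
        alpha[:config.s] = config.alpha_strength
    return alpha, beta


def generate(config: ScenarioConfig):
    """Draw one (dataset, ground truth) pair from the scenario."""
    rng = np.random.default_rng(int(config.seed))
    alpha, beta = _coefficients(rng, config)
    if config.exposure == "binary":
        x = rng.binomial(1, 0.5, size=config.n).astype(float)
        if x.var() == 0.0:                     # degenerate tiny-n draw
            x[0] = 1.0 - x[0]
    else:
        x = rng.standard_normal(config.n)
    n_paired = min(N_BETA_ACTIVE, config.p) if config.corr == "block" else None
    eps_m = _draw_noise(rng, config.n, config.p, config.corr, config.rho,
                        config.pair_size, n_paired)
    m = x[:, None] * alpha + eps_m
    y = config.beta_X * x + m @ beta + rng.standard_normal(config.n)

    names = tuple(f"M{j + 1}" for j in range(config.p))
    contrib = alpha * beta
    truth = GroundTruth(
        alpha_X=alpha, beta_M=beta, beta_X=float(config.beta_X),
        true_ie=float(contrib.sum()),
        active_set=tuple(names[j] for j in np.flatnonzero(contrib)),
    )
    data = MediationDataset(exposure=x, outcome=y, mediators=m,
                            mediator_names=names)
    return data, truth


def replicate_stream(config: ScenarioConfig, n_reps: int, start: int = 0):
    """Independent replicates with deterministic per-index seeds.

    Replicate ``i`` (absolute index ``start + i``) is generated with the
    seed derived from ``(config.seed, start + i)``, so the concatenation of
    streams ``(start=0, k)`` and ``(start=k, k)`` reproduces the length-2k
    stream exactly.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    for i in range(start, start + n_reps):
        child = np.random.SeedSequence((int(config.seed), i)).generate_state(1)[0]
        yield generate(config.replace(seed=int(child) & 0x7FFFFFFF))
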
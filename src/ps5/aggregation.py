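"""Step 3: multiple sample splitting and p-value aggregation.

A single random split is a "p-value lottery": the selected set and the
p-values depend on the partition.  Running R independent splits and
aggregating — the median for effect estimates and global p-values, an
empirical delta-quantile for per-mediator p-values with delta proportional
to each mediator's selection frequency (delta = 0.5 h / R when selected h
times) — yields stable estimates and valid aggregated inference.  FDR and
FWER over the prioritized mediators are controlled by Benjamini-Yekutieli
and Bonferroni, respectively.

Quantiles are type-1 (left-continuous order statistics: the ceil(delta*R)-th
smallest of the length-R vector, with absent splits counted as p = 1), a
convention fixed for bit-reproducibility.  No (1 - log delta) inflation
factor is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from statsmodels.stats.multitest import multipletests

from .config import PS5Config
from .data import MediationDataset
from .inference import SplitFit, test_split
from .linmod import estimate_total_effect, neutralization_ratio
from .selection import mcp_select, remove_marginal_exposure, split_samples

__all__ = [
    "AggregatedResult",
    "run_multi_split",
    "aggregate_global",
    "aggregate_mediator",
    "adjust_pvalues",
]

_SEED_MASK = 0x7FFFFFFF  # keep derived seeds below 2^31


@dataclass(frozen=True)
class AggregatedResult:
    """Multi-split summary of a PS5 analysis."""

    n_splits: int
    ie_median: float
    nde_median: float
    te: float
    gm_pct: float
    nr_median: float
    p_global_agg: float
    per_mediator: pd.DataFrame   # index: mediator id; columns: h, delta,
                                 # p_agg, q_by, p_bonf, contribution_median,
                                 # contribution_share
    split_fits: tuple            # the R SplitFit objects
    master_seed: int
    config: PS5Config

    def summary_dict(self) -> dict:
        """Global summary as plain scalars (JSON-ready)."""
        return {
            "n_splits": self.n_splits,
            "nie": self.ie_median,
            "nde": self.nde_median,
            "te": self.te,
            "gm_pct": self.gm_pct,
            "nr": self.nr_median,
            "p_global": self.p_global_agg,
            "n_mediators_ever_selected": int(self.per_mediator.shape[0]),
            "master_seed": self.master_seed,
            "config": self.config.to_dict(),
        }


def _type1_quantile(values: np.ndarray, delta: float) -> float:
    """Left-continuous empirical quantile: the ceil(delta*R)-th smallest."""
    r = values.size
    k = max(1, math.ceil(delta * r))
    return float(np.sort(values)[k - 1])


def aggregate_global(p_globals) -> float:
    """Median-aggregated global p-value: min{Q(0.5, p), 1}."""
    p = np.asarray(p_globals, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    return min(_type1_quantile(p, 0.5), 1.0)


def aggregate_mediator(p_values_by_split, h: int):
    """delta-quantile aggregation of one mediator's per-split p-values.

    ``p_values_by_split`` has length R with entries of 1 for splits where
    the mediator was not selected; ``h`` is the selection count.  Returns
    (delta, aggregated p).
    """
    p = np.asarray(p_values_by_split, dtype=float).ravel()
    r = p.size
    if not 1 <= h <= r:
        raise ValueError("h must be in 1..R")
    delta = 0.5 * h / r
    return delta, min(_type1_quantile(p, delta), 1.0)


def adjust_pvalues(p, method: str, m: int = None):
    """Multiplicity adjustment over a universe of ``m`` hypotheses.

    ``method`` is "by" (Benjamini-Yekutieli step-up with the harmonic
    correction, monotone, capped at 1) or "bonferroni" (min(m p, 1)).
    When ``m`` exceeds the number of supplied p-values, the remainder are
    treated as p = 1.
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    m = p.size if m is None else int(m)
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    padded = np.concatenate([p, np.ones(m - p.size)])
    key = {"by": "fdr_by", "bonferroni": "bonferroni"}[method.lower()]
    adj = multipletests(padded, method=key)[1]
    return adj[: p.size]


def _child_seeds(master_seed: int, r: int) -> np.ndarray:
    """Counter-based per-split seeds, independent of worker scheduling."""
    state = np.random.SeedSequence(int(master_seed)).generate_state(2 * r)
    return (state & _SEED_MASK).reshape(r, 2)


def _one_split(data, resid, te, seeds, config: PS5Config, cap) -> SplitFit:
    split_seed, mc_seed = (int(s) for s in seeds)
    plan = split_samples(data.n_samples, split_seed)
    selection = mcp_select(
        resid, data.covariates, plan.d1_rows,
        mcp_a=config.mcp_a, seed=split_seed,
        criterion=config.selection_criterion, cv_folds=config.cv_folds,
        n_lambda=config.n_lambda, lambda_min_ratio=config.lambda_min_ratio,
        max_selected=cap, tol=config.cd_tol, max_sweeps=config.cd_max_sweeps,
    )
    return test_split(data, plan, selection, gamma=config.gamma,
                      B=config.mc_draws, seed=mc_seed, te=te)


def run_multi_split(data: MediationDataset, R: int = 50,
                    config: PS5Config = None, master_seed: int = 0,
                    n_jobs: int = 1) -> AggregatedResult:
    """Run the full PS5 pipeline over R independent sample splits.

    Per-split seeds are derived from ``master_seed`` by a counter-based
    scheme, so the result is bit-identical for any worker count.
    """
    if R < 1:
        raise ValueError("R must be at least 1")
    config = config or PS5Config()
    resid = remove_marginal_exposure(data)
    te = estimate_total_effect(data)
    n2 = data.n_samples - data.n_samples // 2
    cap = max(1, n2 // 2 - data.n_covariates - 2)
    seeds = _child_seeds(master_seed, R)

    if n_jobs == 1:
        fits = [_one_split(data, resid, te, seeds[i], config, cap)
                for i in range(R)]
    else:
        fits = Parallel(n_jobs=n_jobs)(
            delayed(_one_split)(data, resid, te, seeds[i], config, cap)
            for i in range(R))

    return _aggregate(data, fits, te, master_seed, config)


def _aggregate(data, fits, te, master_seed, config) -> AggregatedResult:
    r = len(fits)
    p_globals = np.array([f.p_global for f in fits])
    ies = np.array([f.ie for f in fits])
    ndes = np.array([f.effect.nde for f in fits])
    nrs = np.array([f.effect.nr for f in fits])

    ie_median = float(np.median(ies))
    gm = ie_median / te if abs(te) > 1e-10 else float("nan")

    # per-mediator table over everything selected at least once
    per_split_p = {}
    per_split_contrib = {}
    for i, f in enumerate(fits):
        if f.ps is None:
            continue
        for j, name in enumerate(f.ps.mediator_names):
            per_split_p.setdefault(name, {})[i] = f.ps.p_marginal[j]
            per_split_contrib.setdefault(name, []).append(
                f.effect.contributions[j])

    names = [n for n in data.mediator_names if n in per_split_p]
    rows = []
    for name in names:
        pvec = np.ones(r)
        for i, pv in per_split_p[name].items():
            pvec[i] = pv
        h = len(per_split_p[name])
        delta, p_agg = aggregate_mediator(pvec, h)
        rows.append((name, h, delta, p_agg,
                     float(np.median(per_split_contrib[name]))))

    tbl = pd.DataFrame(rows, columns=["mediator", "h", "delta", "p_agg",
                                      "contribution_median"])
    tbl = tbl.set_index("mediator")
    if len(tbl):
        m = len(tbl)  # multiplicity universe: mediators selected at least once
        tbl["q_by"] = adjust_pvalues(tbl["p_agg"].to_numpy(), "by", m)
        tbl["p_bonf"] = adjust_pvalues(tbl["p_agg"].to_numpy(), "bonferroni", m)
        denom = np.abs(tbl["contribution_median"]).sum()
        tbl["contribution_share"] = (
            np.abs(tbl["contribution_median"]) / denom if denom > 0 else 0.0)
        tbl = tbl[["h", "delta", "p_agg", "q_by", "p_bonf",
                   "contribution_median", "contribution_share"]]
    else:
        tbl = pd.DataFrame(columns=["h", "delta", "p_agg", "q_by", "p_bonf",
                                    "contribution_median", "contribution_share"])
        tbl.index.name = "mediator"

    return AggregatedResult(
        n_splits=r,
        ie_median=ie_median,
        nde_median=float(np.median(ndes)),
        te=float(te),
        gm_pct=gm,
        nr_median=float(np.median(nrs)),
        p_global_agg=aggregate_global(p_globals),
        per_mediator=tbl,
        split_fits=tuple(fits),
        master_seed=int(master_seed),
        config=config,
    )
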
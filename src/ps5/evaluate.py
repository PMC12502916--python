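"""Operating-characteristic experiments: type I error, power, bias,
prioritization sensitivity and false positive rate.

Each experiment is a pure function of its configuration and seeds: it
streams replicate datasets from :mod:`ps5.synthdata`, runs the full
multi-split pipeline on each and summarizes the outcome.  Default
experiment scale is deliberately desk-sized (replicates in the tens to
hundreds, R = 20 splits, B = 1000 draws); full-scale runs are reachable
through the same knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregation import AggregatedResult, run_multi_split
from .config import PS5Config
from .synthdata import ScenarioConfig, replicate_stream

__all__ = [
    "OperatingCharacteristics",
    "type1_experiment",
    "power_experiment",
    "prioritization_experiment",
    "rank_mediators",
    "plot_qq",
    "plot_power_curve",
]


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Summary of one replicated experiment."""

    scenario: ScenarioConfig
    n_reps: int
    alpha_level: float
    p_values: np.ndarray = None          # aggregated global p per replicate
    rejection_rate: float = None
    ie_estimates: np.ndarray = None      # median-IE per replicate
    rel_bias: float = None               # |mean(IE_hat) - IE| / IE
    sensitivity_at_k: float = None
    fpr: float = None
    per_replicate: pd.DataFrame = None   # tidy one-row-per-replicate table

    def to_dict(self) -> dict:
        out = {"kind": self.scenario.kind, "n": self.scenario.n,
               "p": self.scenario.p, "n_reps": self.n_reps,
               "alpha_level": self.alpha_level}
        for k in ("rejection_rate", "rel_bias", "sensitivity_at_k", "fpr"):
            v = getattr(self, k)
            if v is not None:
                out[k] = float(v)
        return out


def _master_seeds(scenario_seed: int, n_reps: int) -> np.ndarray:
    state = np.random.SeedSequence((int(scenario_seed), 0x5B5)).generate_state(n_reps)
    return state & 0x7FFFFFFF


def _run_replicates(config: ScenarioConfig, n_reps: int, R: int,
                    ps5_config: PS5Config, n_jobs: int = 1):
    seeds = _master_seeds(config.seed, n_reps)
    for i, (data, truth) in enumerate(replicate_stream(config, n_reps)):
        res = run_multi_split(data, R=R, config=ps5_config,
                              master_seed=int(seeds[i]), n_jobs=n_jobs)
        yield truth, res


def type1_experiment(config: ScenarioConfig, n_reps: int = 300,
                     alpha: float = 0.05, ps5_config: PS5Config = None,
                     R: int = 20, n_jobs: int = 1) -> OperatingCharacteristics:
    """Rejection rate and p-value sample under a null scenario."""
    if config.kind == "alternative":
        raise ValueError("type I error experiments require a null scenario")
    ps5_config = ps5_config or PS5Config.simulation()
    rows = []
    for truth, res in _run_replicates(config, n_reps, R, ps5_config, n_jobs):
        rows.append({"p_global": res.p_global_agg, "ie": res.ie_median})
    tbl = pd.DataFrame(rows)
    p = tbl["p_global"].to_numpy()
    return OperatingCharacteristics(
        scenario=config, n_reps=n_reps, alpha_level=alpha, p_values=p,
        rejection_rate=float(np.mean(p <= alpha)), per_replicate=tbl)


def power_experiment(config: ScenarioConfig, n_reps: int = 50,
                     alpha: float = 0.05, ps5_config: PS5Config = None,
                     R: int = 20, n_jobs: int = 1) -> OperatingCharacteristics:
    """Power of the aggregated global test plus relative bias of median-IE."""
    if config.kind != "alternative":
        raise ValueError("power experiments require the alternative scenario")
    ps5_config = ps5_config or PS5Config.simulation()
    rows = []
    true_ie = None
    for truth, res in _run_replicates(config, n_reps, R, ps5_config, n_jobs):
        true_ie = truth.true_ie
        rows.append({"p_global": res.p_global_agg, "ie": res.ie_median})
    tbl = pd.DataFrame(rows)
    p = tbl["p_global"].to_numpy()
    ies = tbl["ie"].to_numpy()
    rel_bias = (abs(ies.mean() - true_ie) / abs(true_ie)
                if true_ie not in (None, 0.0) else None)
    return OperatingCharacteristics(
        scenario=config, n_reps=n_reps, alpha_level=alpha, p_values=p,
        rejection_rate=float(np.mean(p <= alpha)), ie_estimates=ies,
        rel_bias=rel_bias, per_replicate=tbl)


def rank_mediators(result: AggregatedResult) -> list:
    """Mediator ids ordered best-first by aggregated p-value.

    Ties (e.g. several mediators at the Monte-Carlo floor) are broken by
    selection frequency (higher first) and then by the absolute median
    contribution (larger first).
    """
    tbl = result.per_mediator
    if tbl.empty:
        return []
    order = tbl.assign(_abs=np.abs(tbl["contribution_median"])).sort_values(
        ["p_agg", "h", "_abs"], ascending=[True, False, False])
    return list(order.index)


def prioritization_experiment(config: ScenarioConfig, n_reps: int = 20,
                              k: int = None, q_threshold: float = 0.01,
                              ps5_config: PS5Config = None, R: int = 20,
                              n_jobs: int = 1) -> OperatingCharacteristics:
    """Sensitivity of top-k ranking and FPR at the BY threshold.

    Sensitivity is the mean fraction of the true active mediators appearing
    in the top k of the aggregated ranking (k defaults to the number of
    active mediators); FPR is the mean fraction of inactive mediators among
    those declared significant at ``q_by <= q_threshold`` (0 when nothing
    is declared).
    """
    if config.kind != "alternative":
        raise ValueError("prioritization requires the alternative scenario")
    ps5_config = ps5_config or PS5Config.simulation()
    rows = []
    for truth, res in _run_replicates(config, n_reps, R, ps5_config, n_jobs):
        active = set(truth.active_set)
        if not active and config.s > 0:
            # zero-strength grid point: score against the designated subset
            active = {f"M{j + 1}" for j in range(config.s)}
        kk = len(active) if k is None else k
        ranked = rank_mediators(res)
        top = set(ranked[:kk])
        sens = len(top & active) / len(active) if active else float("nan")
        tbl = res.per_mediator
        declared = set(tbl.index[tbl["q_by"] <= q_threshold]) if len(tbl) else set()
        fpr = (len(declared - active) / len(declared)) if declared else 0.0
        rows.append({"sensitivity": sens, "fpr": fpr,
                     "n_declared": len(declared)})
    tbl = pd.DataFrame(rows)
    return OperatingCharacteristics(
        scenario=config, n_reps=n_reps, alpha_level=q_threshold,
        sensitivity_at_k=float(tbl["sensitivity"].mean()),
        fpr=float(tbl["fpr"].mean()), per_replicate=tbl)


def plot_qq(p_values, path=None, ax=None):
    """Uniform Q-Q plot of p-values on the -log10 scale."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    p = np.sort(np.asarray(p_values, dtype=float))
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(-np.log10(expected), -np.log10(p), "o", ms=3)
    lim = max(-np.log10(expected[0]), -np.log10(max(p[0], 1e-16)))
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_power_curve(table: pd.DataFrame, x: str, y: str = "power",
                     hue: str = None, path=None, ax=None):
    """Line plot of power (or any rate) against a signal parameter."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    if hue is None:
        ax.plot(table[x], table[y], "o-")
    else:
        for key, grp in table.groupby(hue):
            ax.plot(grp[x], grp[y], "o-", label=f"{hue}={key}")
        ax.legend()
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.set_ylim(-0.02, 1.02)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
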
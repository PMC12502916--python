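"""Model/Results facade over the PS5 pipeline.

`PS5Mediation` holds the observed data; its :meth:`fit` runs the
three-step procedure (multiple sample splitting with MCP selection,
partial-sum inference, delta-quantile aggregation) and returns a
:class:`PS5MediationResults` carrying the aggregated estimates, the global
test, the per-mediator prioritization table and a text summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregation import AggregatedResult, run_multi_split
from .config import PS5Config
from .data import MediationDataset, from_dataframe

__all__ = ["PS5Mediation", "PS5MediationResults"]


class PS5Mediation:
    """High-dimensional causal mediation model.

    Parameters
    ----------
    outcome, exposure : array-like, shape (N,)
    mediators : array-like, shape (N, p)
    covariates : array-like, shape (N, l), optional
    mediator_names, covariate_names : sequences of str, optional
    """

    def __init__(self, outcome, exposure, mediators, covariates=None,
                 mediator_names=None, covariate_names=()):
        self.data = MediationDataset(
            exposure=exposure, outcome=outcome, mediators=mediators,
            covariates=covariates, mediator_names=mediator_names,
            covariate_names=covariate_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, exposure: str, outcome: str,
                       mediators=None, mediator_prefix=None, covariates=()):
        """Build the model from a tidy DataFrame by column roles."""
        obj = cls.__new__(cls)
        obj.data = from_dataframe(df, exposure, outcome, mediators=mediators,
                                  mediator_prefix=mediator_prefix,
                                  covariates=covariates)
        return obj

    @classmethod
    def from_dataset(cls, data: MediationDataset):
        obj = cls.__new__(cls)
        obj.data = data
        return obj

    def fit(self, n_splits: int = 50, seed: int = 0, config: PS5Config = None,
            n_jobs: int = 1, **config_overrides) -> "PS5MediationResults":
        """Run the full pipeline over ``n_splits`` sample splits.

        Keyword overrides (``gamma``, ``mc_draws``, ``mcp_a``, ``cv_folds``,
        ...) are applied on top of ``config`` (default :class:`PS5Config`).
        """
        config = (config or PS5Config())
        if config_overrides:
            config = config.replace(**config_overrides)
        agg = run_multi_split(self.data, R=n_splits, config=config,
                              master_seed=seed, n_jobs=n_jobs)
        return PS5MediationResults(self, agg)


class PS5MediationResults:
    """Fitted-model results: aggregated effects, global test, prioritization."""

    def __init__(self, model: PS5Mediation, aggregated: AggregatedResult):
        self.model = model
        self.aggregated = aggregated

    # -- scalar accessors -------------------------------------------------
    @property
    def nie(self) -> float:
        """Global indirect effect (median over splits)."""
        return self.aggregated.ie_median

    @property
    def nde(self) -> float:
        return self.aggregated.nde_median

    @property
    def te(self) -> float:
        return self.aggregated.te

    @property
    def gm_pct(self) -> float:
        """Global mediation percentage NIE/TE (fraction; NaN if TE ~ 0)."""
        return self.aggregated.gm_pct

    @property
    def nr(self) -> float:
        return self.aggregated.nr_median

    @property
    def p_global(self) -> float:
        return self.aggregated.p_global_agg

    @property
    def mediator_table(self) -> pd.DataFrame:
        return self.aggregated.per_mediator

    def significant_mediators(self, q: float = None) -> list:
        """Mediator ids passing the BY threshold (default from config)."""
        q = self.aggregated.config.fdr_q if q is None else q
        tbl = self.mediator_table
        return list(tbl.index[tbl["q_by"] <= q]) if len(tbl) else []

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        a = self.aggregated
        gm = f"{100 * a.gm_pct:10.2f}" if np.isfinite(a.gm_pct) else "  undefined"
        rows = [
            ("samples", f"{self.model.data.n_samples:d}"),
            ("candidate mediators", f"{self.model.data.n_mediators:d}"),
            ("sample splits (R)", f"{a.n_splits:d}"),
            (None, None),
            ("global indirect effect (NIE)", f"{a.ie_median:.5f}"),
            ("direct effect (NDE)", f"{a.nde_median:.5f}"),
            ("total effect (TE)", f"{a.te:.5f}"),
            ("global mediation %", gm.strip()),
            ("neutralization ratio", f"{a.nr_median:.4f}"),
            ("global p-value", f"{a.p_global_agg:.3e}"),
            ("mediators ever selected", f"{len(a.per_mediator):d}"),
        ]
        width = 46
        lines = ["            PS5 mediation analysis", "=" * width]
        for label, value in rows:
            if label is None:
                lines.append("-" * width)
            else:
                lines.append(f"{label:<30s}{value:>16s}")
        lines.append("=" * width)
        return "\n".join(lines)

    def save(self, outdir) -> dict:
        """Write the JSON summary and the per-mediator TSV; return paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary_path = outdir / "summary.json"
        table_path = outdir / "mediators.tsv"
        with open(summary_path, "w") as fh:
            json.dump(self.aggregated.summary_dict(), fh, indent=2)
            fh.write("\n")
        self.mediator_table.to_csv(table_path, sep="\t",
                                   float_format="%.17g")
        return {"summary": str(summary_path), "table": str(table_path)}

    def __repr__(self) -> str:
        return (f"<PS5MediationResults NIE={self.nie:.4g} "
                f"p_global={self.p_global:.3g} R={self.aggregated.n_splits}>")
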
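"""The observed-data container for mediation analysis.

A mediation dataset is a rectangle of N i.i.d. samples holding one exposure
column X (continuous or 0/1), one continuous outcome Y, p mediator columns
M and l >= 0 covariate columns C.  All downstream sample/feature indexing
goes through this container, which validates the contract once at
construction time: equal lengths, no missing values, unique mediator names
and a non-degenerate exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataValidationError

logger = logging.getLogger(__name__)

__all__ = ["MediationDataset", "load_dataset"]


@dataclass(frozen=True)
class MediationDataset:
    """Immutable (X, Y, M, C) rectangle.

    Attributes
    ----------
    exposure : ndarray, shape (N,)
        Exposure X.
    outcome : ndarray, shape (N,)
        Continuous outcome Y.
    mediators : ndarray, shape (N, p)
        Mediator matrix M.
    covariates : ndarray, shape (N, l)
        Covariate matrix C; ``l`` may be zero.
    mediator_names : tuple of str
        Stable, unique column identifiers for the mediators.
    covariate_names : tuple of str
    sample_ids : tuple
        Opaque per-sample identifiers (defaults to 0..N-1).
    """

    exposure: np.ndarray
    outcome: np.ndarray
    mediators: np.ndarray
    covariates: np.ndarray = None
    mediator_names: tuple = None
    covariate_names: tuple = ()
    sample_ids: tuple = None

    def __post_init__(self):
        x = np.asarray(self.exposure, dtype=float).ravel()
        y = np.asarray(self.outcome, dtype=float).ravel()
        m = np.atleast_2d(np.asarray(self.mediators, dtype=float))
        if m.shape[0] == 1 and x.size != 1:
            m = m.T
        c = self.covariates
        if c is None:
            c = np.empty((x.size, 0))
        c = np.asarray(c, dtype=float)
        if c.ndim == 1:
            c = c[:, None]

        n = x.size
        if y.size != n or m.shape[0] != n or c.shape[0] != n:
            raise DataValidationError(
                f"inconsistent sample counts: X={x.size}, Y={y.size}, "
                f"M={m.shape[0]}, C={c.shape[0]}"
            )
        if m.shape[1] < 1:
            raise DataValidationError("at least one mediator column is required")
        for name, arr in (("exposure", x), ("outcome", y), ("mediators", m),
                          ("covariates", c)):
            if not np.all(np.isfinite(arr)):
                raise DataValidationError(f"{name} contains missing/non-finite values")
        if np.var(x) <= 0.0:
            raise DataValidationError(
                "exposure has zero sample variance; no effect is identifiable"
            )

        names = self.mediator_names
        if names is None:
            names = tuple(f"M{j + 1}" for j in range(m.shape[1]))
        names = tuple(map(str, names))
        if len(names) != m.shape[1]:
            raise DataValidationError("mediator_names length does not match M")
        if len(set(names)) != len(names):
            raise DataValidationError("mediator column identifiers must be unique")

        ids = self.sample_ids
        if ids is None:
            ids = tuple(range(n))
        ids = tuple(ids)
        if len(ids) != n:
            raise DataValidationError("sample_ids length does not match N")

        object.__setattr__(self, "exposure", x)
        object.__setattr__(self, "outcome", y)
        object.__setattr__(self, "mediators", m)
        object.__setattr__(self, "covariates", c)
        object.__setattr__(self, "mediator_names", names)
        object.__setattr__(self, "covariate_names", tuple(map(str, self.covariate_names)))
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.exposure.size

    @property
    def n_mediators(self) -> int:
        return self.mediators.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    def mediator_index(self, names) -> np.ndarray:
        """Column indices of the given mediator identifiers (order preserved)."""
        lookup = {name: j for j, name in enumerate(self.mediator_names)}
        try:
            return np.array([lookup[str(n)] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown mediator id {exc.args[0]!r}") from None

    def to_dataframe(self, exposure="X", outcome="Y") -> pd.DataFrame:
        """Flatten back to a tidy table (exposure, outcome, mediators, covariates)."""
        cols = {exposure: self.exposure, outcome: self.outcome}
        for j, name in enumerate(self.mediator_names):
            cols[name] = self.mediators[:, j]
        for j, name in enumerate(self.covariate_names):
            cols[name] = self.covariates[:, j]
        return pd.DataFrame(cols, index=list(self.sample_ids))


def _resolve_mediator_columns(df, mediators=None, mediator_prefix=None):
    if mediators is not None:
        return [str(c) for c in mediators]
    if mediator_prefix is not None:
        cols = [c for c in df.columns if str(c).startswith(mediator_prefix)]
        if not cols:
            raise DataValidationError(
                f"no columns match mediator prefix {mediator_prefix!r}"
            )
        return cols
    raise DataValidationError("either mediators or mediator_prefix must be given")


def from_dataframe(df, exposure, outcome, mediators=None, mediator_prefix=None,
                   covariates=()):
    """Build a :class:`MediationDataset` from a tidy DataFrame.

    Rows containing missing values in any used column are dropped with a
    logged per-column count.  Column roles must be disjoint.
    """
    med_cols = _resolve_mediator_columns(df, mediators, mediator_prefix)
    cov_cols = [str(c) for c in covariates]
    roles = [exposure, outcome, *med_cols, *cov_cols]
    if len(set(roles)) != len(roles):
        dupes = sorted({c for c in roles if roles.count(c) > 1})
        raise DataValidationError(f"column role collision: {dupes}")
    missing = [c for c in roles if c not in df.columns]
    if missing:
        raise DataValidationError(f"columns not found in input: {missing}")

    used = df[roles].apply(pd.to_numeric, errors="coerce")
    bad = used.isna()
    if bad.to_numpy().any():
        per_col = bad.sum()
        per_col = per_col[per_col > 0]
        n_drop = int(bad.any(axis=1).sum())
        logger.warning(
            "dropping %d row(s) with missing/non-numeric values; per-column counts: %s",
            n_drop, per_col.to_dict(),
        )
        used = used[~bad.any(axis=1)]
    if used.shape[0] == 0:
        raise DataValidationError("no usable rows after removing missing values")

    return MediationDataset(
        exposure=used[exposure].to_numpy(),
        outcome=used[outcome].to_numpy(),
        mediators=used[med_cols].to_numpy(),
        covariates=used[cov_cols].to_numpy() if cov_cols else None,
        mediator_names=tuple(med_cols),
        covariate_names=tuple(cov_cols),
        sample_ids=tuple(used.index),
    )


def load_dataset(path, exposure, outcome, mediators=None, mediator_prefix=None,
                 covariates=(), delimiter=None):
    """Read a CSV/TSV file (delimiter sniffed unless given) into a dataset."""
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    return from_dataframe(df, exposure, outcome, mediators=mediators,
                          mediator_prefix=mediator_prefix, covariates=covariates)
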
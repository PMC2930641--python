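"""Survival dataset container and delimited-text loaders.

The on-disk convention is two delimited files: a covariate matrix
(samples x features, header row of feature IDs, first column ``sample_id``)
and a survival table with columns ``sample_id``, ``time``, ``event``.
Rows are matched by sample ID, so the two files may list samples in any
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset", "load_dataset", "write_dataset"]


@dataclass
class SurvivalDataset:
    """Right-censored survival data with covariates.

    Parameters
    ----------
    X : ndarray of shape (n, m)
        Covariate matrix (e.g. gene expression), one row per sample.
    t : ndarray of shape (n,)
        Follow-up times: the event time when ``delta == 1``, the censoring
        time when ``delta == 0``. Nonnegative.
    delta : ndarray of shape (n,)
        Event indicators in {0, 1}; 1 means the event (death) was observed.
    feature_ids : list of str
        Column labels for ``X``.
    sample_ids : list of str, optional
        Row labels; defaults to ``s0..s{n-1}``.
    """

    X: np.ndarray
    t: np.ndarray
    delta: np.ndarray
    feature_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix (samples x features)")
        self.t = np.asarray(self.t, dtype=float)
        self.delta = np.asarray(self.delta)
        n = self.X.shape[0]
        if n < 2:
            raise ValueError("need at least two samples")
        if len(self.t) != n or len(self.delta) != n:
            raise ValueError("t, delta and rows of X must have equal length")
        if np.any(~np.isfinite(self.X)) or np.any(~np.isfinite(self.t)):
            raise ValueError("missing or non-finite values in data")
        if np.any(self.t < 0):
            raise ValueError("survival times must be nonnegative")
        if not np.isin(self.delta, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        self.delta = self.delta.astype(int)
        if not self.feature_ids:
            self.feature_ids = [f"x{j + 1}" for j in range(self.X.shape[1])]
        if len(self.feature_ids) != self.X.shape[1]:
            raise ValueError("feature_ids length must match columns of X")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match rows of X")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.delta.sum())

    def subset(self, rows: np.ndarray) -> "SurvivalDataset":
        """Return the dataset restricted to the given row indices."""
        rows = np.asarray(rows)
        return SurvivalDataset(
            X=self.X[rows],
            t=self.t[rows],
            delta=self.delta[rows],
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in rows],
        )

    def standardized(self) -> "SurvivalDataset":
        """Per-feature standardization to mean 0, variance 1.

        Constant features are left at zero rather than dividing by a zero
        standard deviation.
        """
        mu = self.X.mean(axis=0)
        sd = self.X.std(axis=0)
        sd[sd == 0] = 1.0
        return SurvivalDataset(
            X=(self.X - mu) / sd,
            t=self.t,
            delta=self.delta,
            feature_ids=list(self.feature_ids),
            sample_ids=list(self.sample_ids),
        )


def _read_table(path: str, sep: str | None) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, engine="python")


def load_dataset(
    expr_path: str,
    surv_path: str,
    sep: str | None = None,
    standardize: bool = False,
    log2_transform: bool = False,
) -> SurvivalDataset:
    """Load covariates and survival outcomes, matching rows by sample ID.

    Parameters
    ----------
    expr_path : str
        Covariate matrix: first column ``sample_id``, remaining columns one
        per feature. Tab- or comma-delimited (sniffed when ``sep`` is None).
    surv_path : str
        Survival table with columns ``sample_id``, ``time``, ``event``.
    standardize : bool
        Scale every feature to mean 0, variance 1 (typical microarray
        preprocessing). Leave off for simulated data.
    log2_transform : bool
        Apply log2(x) before standardization (raw intensity data); applied
        before standardization.
    """
    expr = _read_table(expr_path, sep)
    surv = _read_table(surv_path, sep)
    expr_ids = expr.iloc[:, 0].astype(str)
    if expr_ids.duplicated().any():
        dup = expr_ids[expr_ids.duplicated()].iloc[0]
        raise ValueError(f"duplicate sample_id in expression file: {dup!r}")
    expr = expr.set_index(expr.columns[0])
    feature_ids = [str(c) for c in expr.columns]
    if len(set(feature_ids)) != len(feature_ids):
        raise ValueError("duplicate feature names in expression header")
    for col in ("sample_id", "time", "event"):
        if col not in surv.columns:
            raise ValueError(f"survival table missing column {col!r}")
    surv = surv.copy()
    surv["sample_id"] = surv["sample_id"].astype(str)
    surv = surv.set_index("sample_id")

    missing_in_surv = set(expr.index.astype(str)) - set(surv.index)
    if missing_in_surv:
        raise ValueError(
            "samples present in expression but not in survival table: "
            + ", ".join(sorted(missing_in_surv)[:5])
        )
    missing_in_expr = set(surv.index) - set(expr.index.astype(str))
    if missing_in_expr:
        raise ValueError(
            "samples present in survival table but not in expression: "
            + ", ".join(sorted(missing_in_expr)[:5])
        )
    surv = surv.loc[expr.index.astype(str)]

    try:
        X = expr.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in expression matrix: {exc}") from exc
    if log2_transform:
        if np.any(X <= 0):
            raise ValueError("log2 transform requires strictly positive values")
        X = np.log2(X)
    ds = SurvivalDataset(
        X=X,
        t=surv["time"].to_numpy(dtype=float),
        delta=surv["event"].to_numpy(),
        feature_ids=feature_ids,
        sample_ids=[str(s) for s in expr.index],
    )
    return ds.standardized() if standardize else ds


def write_dataset(ds: SurvivalDataset, expr_path: str, surv_path: str) -> None:
    """Write a dataset to the paired expression/survival text format."""
    expr = pd.DataFrame(ds.X, columns=ds.feature_ids)
    expr.insert(0, "sample_id", ds.sample_ids)
    expr.to_csv(expr_path, sep="\t", index=False)
    surv = pd.DataFrame(
        {"sample_id": ds.sample_ids, "time": ds.t, "event": ds.delta}
    )
    surv.to_csv(surv_path, sep="\t", index=False)
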
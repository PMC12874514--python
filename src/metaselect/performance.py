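"""Bias, RMSE, and coverage of the estimators, with two-stage aggregation.

Metrics are first computed within each DGP (over its replicate datasets)
and the per-DGP values are then averaged across DGPs — equally weighted by
default, or with a supplied weight vector (the reweighted-performance
path).  The staging matters for RMSE: the average of per-DGP RMSEs is not
the pooled RMSE, and it is the former that is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import FitResult

__all__ = ["PerformanceSummary", "per_dgp_metrics", "aggregate_metrics"]

logger = logging.getLogger(__name__)

#: columns expected of a per-DGP metrics table
PER_DGP_COLUMNS = ("dgp_id", "dgp_type", "estimator", "bias", "rmse", "coverage")


@dataclass(frozen=True)
class PerformanceSummary:
    """Aggregated metrics for one (group, estimator) cell.

    ``group`` is "ALL" or one of the four DGP types; ``coverage`` is the
    percentage of nominal confidence intervals containing the true effect.
    """

    group: str
    estimator: str
    bias: float
    rmse: float
    coverage: float


def per_dgp_metrics(
    fits: Sequence[FitResult], true_mu: float
) -> tuple[float, float, float]:
    """(bias, rmse, coverage%) of one estimator over one DGP's replicates."""
    if not fits:
        raise ValueError("no fits supplied")
    mu = np.array([f.mu_hat for f in fits])
    lo = np.array([f.ci_low for f in fits])
    hi = np.array([f.ci_high for f in fits])
    return _metrics_from_arrays(mu, lo, hi, true_mu)


def _metrics_from_arrays(
    mu_hat: np.ndarray, ci_low: np.ndarray, ci_high: np.ndarray, true_mu: float
) -> tuple[float, float, float]:
    err = mu_hat - true_mu
    bias = float(err.mean())
    rmse = float(np.sqrt(np.mean(err * err)))
    coverage = 100.0 * float(np.mean((ci_low <= true_mu) & (true_mu <= ci_high)))
    return bias, rmse, coverage


def aggregate_metrics(
    per_dgp: pd.DataFrame,
    weights: Optional[Mapping[int, float]] = None,
) -> list[PerformanceSummary]:
    """Average per-DGP metrics across DGPs, for ALL and each type subgroup.

    Parameters
    ----------
    per_dgp
        One row per (dgp_id, estimator) with columns ``PER_DGP_COLUMNS``.
    weights
        Optional non-negative weights keyed by dgp_id (e.g. match counts
        from the reweighting module, normalised or not).  Within each group
        the weights are renormalised over that group's DGPs; a group with
        zero total weight falls back to equal weights.

    Every estimator must have a metrics row for every DGP in the table.
    """
    missing = [c for c in PER_DGP_COLUMNS if c not in per_dgp.columns]
    if missing:
        raise ValueError(f"per_dgp table missing columns: {missing}")
    counts = per_dgp.groupby("estimator")["dgp_id"].nunique()
    n_dgps = per_dgp["dgp_id"].nunique()
    if (counts != n_dgps).any():
        raise ValueError("missing (dgp, estimator) cells in per-DGP metrics")

    if weights is not None:
        w = pd.Series(dict(weights), dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        wcol = per_dgp["dgp_id"].map(w).fillna(0.0)
    else:
        wcol = pd.Series(1.0, index=per_dgp.index)
    df = per_dgp.assign(_w=wcol.to_numpy())

    summaries: list[PerformanceSummary] = []
    groups = [("ALL", df)] + [
        (t, sub) for t, sub in df.groupby("dgp_type", sort=True)
    ]
    for name, sub in groups:
        for est, cell in sub.groupby("estimator", sort=True):
            w = cell["_w"].to_numpy()
            if w.sum() <= 0:
                logger.warning(
                    "group %s has zero total weight; using equal weights", name
                )
                w = np.ones_like(w)
            w = w / w.sum()
            summaries.append(
                PerformanceSummary(
                    group=name,
                    estimator=est,
                    bias=float(w @ cell["bias"].to_numpy()),
                    rmse=float(w @ cell["rmse"].to_numpy()),
                    coverage=float(w @ cell["coverage"].to_numpy()),
                )
            )
    return summaries
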
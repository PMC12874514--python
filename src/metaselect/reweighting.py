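"""Mahalanobis matching of empirical parameter estimates to grid DGPs.

Given a cloud of fitted (mu_hat, gamma_hat, tau2_hat, N) points — one per
real meta-analysis — each point is matched to its nearest grid DGP under
the Mahalanobis metric, with the covariance estimated from the pooled
cloud.  The match counts, normalised to sum to one, provide a weight vector
that re-aggregates simulation performance to reflect how often each
simulated world actually occurs in a corpus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dgp import DGPSpec

__all__ = [
    "ParameterPoint",
    "mahalanobis_match",
    "read_point_cloud",
    "write_weights",
    "read_weights",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParameterPoint:
    """One meta-analysis summarised by its fitted DGP-like parameters."""

    mu_hat: float
    gamma_hat: float
    tau2_hat: float
    n_studies: int

    def __post_init__(self) -> None:
        vals = (self.mu_hat, self.gamma_hat, self.tau2_hat, float(self.n_studies))
        if not all(np.isfinite(vals)):
            raise ValueError("parameter point entries must be finite")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")


def _point_matrix(points: Sequence[ParameterPoint]) -> np.ndarray:
    return np.array(
        [[p.mu_hat, p.gamma_hat, p.tau2_hat, float(p.n_studies)] for p in points]
    )


def _grid_matrix(grid: Sequence[DGPSpec]) -> np.ndarray:
    return np.array(
        [[s.mu, s.gamma, s.tau2, float(s.n_studies)] for s in grid]
    )


def mahalanobis_match(
    points: Sequence[ParameterPoint], grid: Sequence[DGPSpec]
) -> dict[int, float]:
    """Match each point to its Mahalanobis-nearest grid DGP; return weights.

    The 4x4 covariance is estimated from the pooled point cloud over the raw
    (mu, gamma, tau2, N) coordinates.  If it is singular (e.g. a constant
    coordinate), matching falls back to per-coordinate variance scaling with
    zero variances replaced by 1, and the fallback is logged.  Distance ties
    are broken toward the lowest dgp_id.  The returned map covers every grid
    node; weights are match counts divided by the number of points.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points to estimate a covariance")
    if not grid:
        raise ValueError("empty grid")
    order = np.argsort([s.dgp_id for s in grid], kind="stable")
    grid = [grid[i] for i in order]

    x = _point_matrix(points)
    g = _grid_matrix(grid)
    cov = np.cov(x, rowvar=False)
    try:
        if np.linalg.cond(cov) > 1e12:
            raise np.linalg.LinAlgError("ill-conditioned covariance")
        vi = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        var = np.diag(cov).copy()
        var[var <= 0] = 1.0
        vi = np.diag(1.0 / var)
        logger.warning(
            "singular point-cloud covariance; falling back to diagonal "
            "variance scaling"
        )

    # d^2(p, g) = (p-g) VI (p-g)^T for every point/node pair
    diff = x[:, None, :] - g[None, :, :]
    d2 = np.einsum("pni,ij,pnj->pn", diff, vi, diff)
    nearest = np.argmin(d2, axis=1)  # first minimum -> lowest dgp_id

    counts = np.bincount(nearest, minlength=len(grid)).astype(float)
    weights = counts / counts.sum()
    return {spec.dgp_id: float(w) for spec, w in zip(grid, weights)}


def read_point_cloud(path) -> list[ParameterPoint]:
    """Read a point cloud CSV with columns mu, gamma, tau2, n."""
    df = pd.read_csv(path)
    required = ["mu", "gamma", "tau2", "n"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"point cloud CSV missing columns: {missing}")
    return [
        ParameterPoint(row.mu, row.gamma, row.tau2, int(row.n))
        for row in df.itertuples()
    ]


def write_weights(weights: Mapping[int, float], path) -> None:
    """Write a weight vector CSV with columns dgp_id, weight."""
    pd.DataFrame(
        {"dgp_id": list(weights.keys()), "weight": list(weights.values())}
    ).sort_values("dgp_id").to_csv(path, index=False)


def read_weights(path) -> dict[int, float]:
    """Read a weight vector CSV (dgp_id, weight), e.g. one supplied by a
    user who has fit a real corpus."""
    df = pd.read_csv(path)
    missing = [c for c in ("dgp_id", "weight") if c not in df.columns]
    if missing:
        raise ValueError(f"weights CSV missing columns: {missing}")
    return {int(r.dgp_id): float(r.weight) for r in df.itertuples()}
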
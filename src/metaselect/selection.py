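"""AIC/BIC computation, per-dataset winners, and selection-rate aggregation.

Smaller criterion values are preferred.  Winners are the argmin over the
four candidate models; exact ties (probability zero with continuous data,
but made deterministic anyway) are broken by the fixed order FE, RE,
UWLS_FE, UWLS_RE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import MODELS, FitResult

__all__ = [
    "SelectionRecord",
    "aic",
    "bic",
    "select_best",
    "preference_rate",
    "success_rate",
    "average_ic_table",
]


def aic(fit: FitResult) -> float:
    """Akaike information criterion, 2k - 2*loglik."""
    return 2.0 * fit.n_params - 2.0 * fit.loglik


def bic(fit: FitResult, n_studies: int) -> float:
    """Bayesian information criterion, k*log(N) - 2*loglik (natural log).

    N is the number of studies in the meta-analysis — the sample size the
    criterion's asymptotics refer to.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    return fit.n_params * float(np.log(n_studies)) - 2.0 * fit.loglik


def select_best(scores: Mapping[str, float]) -> str:
    """Argmin over a criterion map; ties broken by the fixed model order."""
    if not scores:
        raise ValueError("empty criterion map")
    order = {m: i for i, m in enumerate(MODELS)}
    return min(scores, key=lambda m: (scores[m], order.get(m, len(order))))


@dataclass(frozen=True)
class SelectionRecord:
    """Per-dataset criterion values for all four models plus the winners."""

    dataset_id: int
    dgp_id: int
    true_type: str
    aic: Mapping[str, float]
    bic: Mapping[str, float]
    winner_aic: str
    winner_bic: str

    @classmethod
    def from_fits(
        cls,
        dataset_id: int,
        dgp_id: int,
        true_type: str,
        fits: Mapping[str, FitResult],
        n_studies: int,
    ) -> "SelectionRecord":
        a = {m: aic(f) for m, f in fits.items()}
        b = {m: bic(f, n_studies) for m, f in fits.items()}
        return cls(dataset_id, dgp_id, true_type, a, b, select_best(a), select_best(b))


def _criterion_maps(records: Sequence[SelectionRecord], criterion: str):
    if criterion not in ("aic", "bic"):
        raise ValueError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    return [getattr(r, criterion) for r in records]


def preference_rate(
    records: Sequence[SelectionRecord], a: str, b: str, criterion: str = "aic"
) -> float:
    """Percentage of datasets where model ``a`` beats model ``b``.

    Strict inequality: ties count against the focal model ``a``.
    """
    if not records:
        raise ValueError("no records")
    maps = _criterion_maps(records, criterion)
    wins = sum(1 for m in maps if m[a] < m[b])
    return 100.0 * wins / len(records)


def success_rate(
    records: Sequence[SelectionRecord], criterion: str = "aic"
) -> dict[str, float]:
    """Percentage of datasets, per true DGP type, whose winner is the truth."""
    if criterion not in ("aic", "bic"):
        raise ValueError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    winner_attr = "winner_" + criterion
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    for r in records:
        totals[r.true_type] = totals.get(r.true_type, 0) + 1
        if getattr(r, winner_attr) == r.true_type:
            hits[r.true_type] = hits.get(r.true_type, 0) + 1
    return {t: 100.0 * hits.get(t, 0) / n for t, n in totals.items()}


def average_ic_table(
    records: Sequence[SelectionRecord],
    criterion: str = "aic",
    grouping: Optional[str] = None,
) -> pd.DataFrame:
    """Mean criterion value per model, ranked best (smallest) first.

    ``grouping=None`` pools all records into one "ALL" group;
    ``grouping="true_type"`` produces one ranked block per DGP type.
    Averaging across meta-analyses of different N mixes criterion scales,
    which is reproduced deliberately: it is how the headline comparison is
    framed.
    """
    if not records:
        raise ValueError("no records")
    maps = _criterion_maps(records, criterion)
    if grouping is None:
        groups = ["ALL"] * len(records)
    elif grouping == "true_type":
        groups = [r.true_type for r in records]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    df = pd.DataFrame(
        [
            {"group": g, "model": m, "value": cm[m]}
            for g, cm in zip(groups, maps)
            for m in cm
        ]
    )
    out = (
        df.groupby(["group", "model"], sort=False)["value"]
        .mean()
        .reset_index()
        .rename(columns={"value": "mean_ic"})
    )
    order = {m: i for i, m in enumerate(MODELS)}
    out["_tie"] = out["model"].map(order)
    out = (
        out.sort_values(["group", "mean_ic", "_tie"], kind="mergesort")
        .drop(columns="_tie")
        .reset_index(drop=True)
    )
    out.insert(0, "criterion", criterion)
    return out
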
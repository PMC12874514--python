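"""Experiment orchestration: the main 108-DGP study and the sample-size sweep.

`run_main_experiment` simulates `replicates_per_dgp` datasets from each of
the 108 grid DGPs, fits all four estimators to every dataset, and returns
per-dataset estimates, per-dataset model-selection records, per-DGP
bias/RMSE/coverage, and the two-stage aggregated summaries.

`run_samplesize_sweep` repeats the model-selection part of the study with
the 36 (mu, gamma, tau2) combinations instantiated at each of a list of
sample sizes, tabulating AIC/BIC correct-selection rates by DGP type.

Randomness: every (experiment, dgp, replicate) cell draws from its own
keyed substream of the master seed, so results are reproducible and
independent of execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .dgp import (
    DGPSpec,
    build_parameter_grid,
    build_sweep_grid,
    grid_to_frame,
    simulate_dataset,
    substream,
)
from .estimators import MODELS, fit_fe, fit_re_ml, fit_uwls_fe, fit_uwls_re
from .performance import PerformanceSummary, aggregate_metrics
from .selection import (
    SelectionRecord,
    average_ic_table,
    preference_rate,
    select_best,
    success_rate,
)

__all__ = [
    "ExperimentConfig",
    "MainExperimentResult",
    "run_main_experiment",
    "run_samplesize_sweep",
    "write_main_tables",
    "write_sweep_table",
    "summaries_to_frame",
]

logger = logging.getLogger(__name__)

# substream experiment tags, so the main run and each sweep size never share
# random numbers
_EXP_MAIN = 0
_EXP_SWEEP = 1


@dataclass
class ExperimentConfig:
    """Knobs of a simulation run.

    ``replicates_per_dgp`` defaults to the study's 1000 datasets per DGP; a
    reduced value (e.g. 200) gives a fast approximate run with wider Monte
    Carlo error.  ``sweep_sizes`` are the per-meta-analysis study counts for
    the sample-size sweep.
    """

    master_seed: int = 20260205
    replicates_per_dgp: int = 1000
    sweep_sizes: tuple[int, ...] = (3, 5, 10, 100, 500, 1000, 5000)
    output_dir: Optional[Path] = None
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.replicates_per_dgp < 1:
            raise ValueError("replicates_per_dgp must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.output_dir is not None:
            self.output_dir = Path(self.output_dir)
        self.sweep_sizes = tuple(int(n) for n in self.sweep_sizes)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class MainExperimentResult:
    """Everything the main run produces."""

    config: ExperimentConfig
    grid: list[DGPSpec]
    records: list[SelectionRecord]
    estimates: pd.DataFrame  # one row per (dataset, model)
    per_dgp: pd.DataFrame    # one row per (dgp, estimator)
    summaries: list[PerformanceSummary]
    exclusions: pd.DataFrame = field(default_factory=pd.DataFrame)


def _fit_dataset(data, level, dgp_id, rep):
    """Fit all four models, logging and excluding individual failures."""
    fits = {}
    failures = []
    fe = re = None
    for model in MODELS:
        try:
            if model == "FE":
                fe = fit_fe(data, level)
                fits["FE"] = fe
            elif model == "RE":
                re = fit_re_ml(data, level)
                fits["RE"] = re
            elif model == "UWLS_FE":
                fits["UWLS_FE"] = fit_uwls_fe(data, level, _fe=fe)
            else:
                fits["UWLS_RE"] = fit_uwls_re(data, level, _re=re)
        except Exception as exc:  # pragma: no cover - fits never fail on grid data
            logger.warning("fit failure dgp=%s rep=%s model=%s: %s", dgp_id, rep, model, exc)
            failures.append({"dgp_id": dgp_id, "replicate": rep, "model": model,
                             "error": str(exc)})
    return fits, failures


def _simulate_and_fit(
    grid: Sequence[DGPSpec], config: ExperimentConfig, exp_key: tuple[int, ...]
) -> tuple[list[SelectionRecord], pd.DataFrame, list[dict]]:
    """Shared core loop: simulate, fit, record."""
    from .selection import aic as _aic, bic as _bic

    cols: dict[str, list] = {
        k: []
        for k in (
            "dataset_id", "dgp_id", "replicate", "model", "mu_hat", "se_mu",
            "tau2_hat", "gamma_hat", "loglik", "n_params", "ci_low", "ci_high",
            "aic", "bic",
        )
    }
    records: list[SelectionRecord] = []
    failures: list[dict] = []
    dataset_id = 0
    for spec in grid:
        for rep in range(config.replicates_per_dgp):
            rng = substream(config.master_seed, *exp_key, spec.dgp_id, rep)
            data = simulate_dataset(spec, rng)
            fits, fails = _fit_dataset(data, config.ci_level, spec.dgp_id, rep)
            failures.extend(fails)
            a = {m: _aic(f) for m, f in fits.items()}
            b = {m: _bic(f, spec.n_studies) for m, f in fits.items()}
            for m, f in fits.items():
                cols["dataset_id"].append(dataset_id)
                cols["dgp_id"].append(spec.dgp_id)
                cols["replicate"].append(rep)
                cols["model"].append(m)
                cols["mu_hat"].append(f.mu_hat)
                cols["se_mu"].append(f.se_mu)
                cols["tau2_hat"].append(f.tau2_hat)
                cols["gamma_hat"].append(f.gamma_hat)
                cols["loglik"].append(f.loglik)
                cols["n_params"].append(f.n_params)
                cols["ci_low"].append(f.ci_low)
                cols["ci_high"].append(f.ci_high)
                cols["aic"].append(a[m])
                cols["bic"].append(b[m])
            if len(fits) == len(MODELS):
                records.append(
                    SelectionRecord(
                        dataset_id, spec.dgp_id, spec.dgp_type,
                        a, b, select_best(a), select_best(b),
                    )
                )
            dataset_id += 1
    return records, pd.DataFrame(cols), failures


def per_dgp_table(estimates: pd.DataFrame, grid: Sequence[DGPSpec]) -> pd.DataFrame:
    """Per-(dgp, estimator) bias/RMSE/coverage from a per-dataset table."""
    gf = grid_to_frame(grid)[["dgp_id", "mu", "dgp_type"]].rename(
        columns={"mu": "true_mu"}
    )
    df = estimates.merge(gf, on="dgp_id", how="left")
    err = df["mu_hat"] - df["true_mu"]
    df = df.assign(
        _err=err,
        _err2=err**2,
        _cov=((df["ci_low"] <= df["true_mu"]) & (df["true_mu"] <= df["ci_high"])).astype(float),
    )
    out = (
        df.groupby(["dgp_id", "dgp_type", "model"], sort=True)
        .agg(bias=("_err", "mean"), mse=("_err2", "mean"), coverage=("_cov", "mean"))
        .reset_index()
        .rename(columns={"model": "estimator"})
    )
    out["rmse"] = np.sqrt(out.pop("mse"))
    out["coverage"] *= 100.0
    return out[["dgp_id", "dgp_type", "estimator", "bias", "rmse", "coverage"]]


def run_main_experiment(
    config: ExperimentConfig,
    weights: Optional[Mapping[int, float]] = None,
) -> MainExperimentResult:
    """Run the full factorial study and aggregate all reported tables.

    With ``weights`` supplied (a dgp_id -> weight map, e.g. from
    Mahalanobis matching of a real corpus), the performance summaries are
    additionally computed under that weighting and written alongside the
    equal-weight tables.
    """
    grid = build_parameter_grid()
    logger.info(
        "main experiment: %d DGPs x %d replicates, seed=%d",
        len(grid), config.replicates_per_dgp, config.master_seed,
    )
    records, estimates, failures = _simulate_and_fit(grid, config, (_EXP_MAIN, 0))
    per_dgp = per_dgp_table(estimates, grid)
    summaries = aggregate_metrics(per_dgp)
    exclusions = pd.DataFrame(failures)
    if len(exclusions):
        logger.warning("%d fit exclusions", len(exclusions))
    result = MainExperimentResult(
        config=config, grid=grid, records=records, estimates=estimates,
        per_dgp=per_dgp, summaries=summaries, exclusions=exclusions,
    )
    if config.output_dir is not None:
        write_main_tables(result, weights=weights)
    return result


def run_samplesize_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Correct-selection rates by sample size, DGP type, and criterion.

    Returns a long table with columns sample_size, dgp_type, criterion,
    success_pct, n_datasets.
    """
    rows = []
    for n in config.sweep_sizes:
        grid = build_sweep_grid(n)
        logger.info(
            "sweep size %d: %d DGPs x %d replicates", n, len(grid),
            config.replicates_per_dgp,
        )
        records, _, _ = _simulate_and_fit(grid, config, (_EXP_SWEEP, n))
        counts: dict[str, int] = {}
        for r in records:
            counts[r.true_type] = counts.get(r.true_type, 0) + 1
        for criterion in ("aic", "bic"):
            rates = success_rate(records, criterion)
            for dgp_type, pct in sorted(rates.items()):
                rows.append(
                    {
                        "sample_size": n,
                        "dgp_type": dgp_type,
                        "criterion": criterion,
                        "success_pct": pct,
                        "n_datasets": counts[dgp_type],
                    }
                )
    table = pd.DataFrame(rows)
    if config.output_dir is not None:
        write_sweep_table(table, config.output_dir)
    return table


def summaries_to_frame(
    summaries: Sequence[PerformanceSummary], weighting: str = "equal"
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [s.group for s in summaries],
            "estimator": [s.estimator for s in summaries],
            "bias": [s.bias for s in summaries],
            "rmse": [s.rmse for s in summaries],
            "coverage": [s.coverage for s in summaries],
            "weighting": weighting,
        }
    )


def write_main_tables(
    result: MainExperimentResult, weights: Optional[Mapping[int, float]] = None
) -> None:
    """Write the study tables (long-format CSVs) into config.output_dir."""
    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    grid_to_frame(result.grid).to_csv(out / "grid.csv", index=False)
    result.estimates.to_csv(out / "estimates.csv", index=False)

    # headline: pooled mean IC ranking plus pairwise preference rates
    t4_blocks = [average_ic_table(result.records, c) for c in ("aic", "bic")]
    t4 = pd.concat(t4_blocks, ignore_index=True)
    t4["metric"] = "mean_ic"
    prefs = [
        {"criterion": c, "group": "ALL", "model": f"UWLS_FE_vs_{other}",
         "mean_ic": np.nan, "metric": "preference_pct",
         "value": preference_rate(result.records, "UWLS_FE", other, c)}
        for c in ("aic", "bic")
        for other in ("RE", "FE")
    ]
    t4["value"] = t4["mean_ic"]
    t4 = pd.concat([t4, pd.DataFrame(prefs)], ignore_index=True)
    t4[["criterion", "group", "model", "metric", "value"]].to_csv(
        out / "table4.csv", index=False
    )

    # per-type IC ranking and correct-selection rates
    t5_blocks = []
    for c in ("aic", "bic"):
        blk = average_ic_table(result.records, c, grouping="true_type")
        blk["metric"] = "mean_ic"
        blk["value"] = blk["mean_ic"]
        t5_blocks.append(blk)
        rates = success_rate(result.records, c)
        t5_blocks.append(
            pd.DataFrame(
                [
                    {"criterion": c, "group": t, "model": t,
                     "metric": "success_pct", "value": pct}
                    for t, pct in sorted(rates.items())
                ]
            )
        )
    pd.concat(t5_blocks, ignore_index=True)[
        ["criterion", "group", "model", "metric", "value"]
    ].to_csv(out / "table5.csv", index=False)

    summaries_to_frame(result.summaries).to_csv(out / "table7a.csv", index=False)
    if weights is not None:
        weighted = aggregate_metrics(result.per_dgp, weights=weights)
        summaries_to_frame(weighted, weighting="mahalanobis").to_csv(
            out / "table7b.csv", index=False
        )
    if len(result.exclusions):
        result.exclusions.to_csv(out / "exclusions.csv", index=False)
    logger.info("tables written to %s", out)


def write_sweep_table(table: pd.DataFrame, output_dir) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "table6.csv", index=False)
    logger.info("sweep table written to %s", out / "table6.csv")
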
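"""Data-generating processes for simulated meta-analyses.

A simulated "world" is one configuration of four parameters:

* ``mu``    — population mean effect (effect-size scale),
* ``gamma`` — multiplicative scale factor on the baseline variance,
* ``tau2``  — additive between-study variance of true effects,
* ``N``     — number of studies per meta-analysis,

together with a fixed vector of within-study sampling SDs ``sigma_i``
calibrated to typical medical meta-analyses.  A study effect is drawn as

    y_i = mu + u_i + eps_i,   u_i ~ N(0, gamma * tau2),
                              eps_i ~ N(0, gamma * sigma_i^2),

so that Var(y_i) = gamma * (sigma_i^2 + tau2).  The factorial grid
(4 mu x 3 gamma x 3 tau2 x 3 N = 108 configurations) is classified into
four heterogeneity types by (gamma, tau2):

    FE       gamma = 1,  tau2 = 0     (12 configurations)
    RE       gamma = 1,  tau2 > 0     (24)
    UWLS_FE  gamma != 1, tau2 = 0     (24)
    UWLS_RE  gamma != 1, tau2 > 0     (48)

Crucially, the estimators are always handed the *unscaled* ``sigma_i``:
``gamma`` is a latent distortion of the reported sampling variances, which
is exactly what the UWLS family of estimators is designed to absorb.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MU_VALUES",
    "GAMMA_VALUES",
    "TAU2_VALUES",
    "N_VALUES",
    "DGP_TYPES",
    "DGPSpec",
    "MetaDataset",
    "classify_dgp",
    "sigma_profile",
    "build_parameter_grid",
    "build_sweep_grid",
    "simulate_dataset",
    "substream",
    "grid_to_frame",
]

# Factorial design: values chosen as representative of the parameter
# distributions seen across a large corpus of medical meta-analyses.
MU_VALUES: tuple[float, ...] = (0.0, 0.25, 0.50, 1.00)
GAMMA_VALUES: tuple[float, ...] = (0.5, 1.0, 1.5)
TAU2_VALUES: tuple[float, ...] = (0.0, 0.01, 0.10)
N_VALUES: tuple[int, ...] = (3, 5, 10)

DGP_TYPES: tuple[str, ...] = ("FE", "RE", "UWLS_FE", "UWLS_RE")

# Calibrated within-study sampling SDs, ordered smallest to largest.
_SIGMA_TABLE: dict[int, tuple[float, ...]] = {
    3: (0.30, 0.40, 0.50),
    5: (0.20, 0.30, 0.40, 0.50, 0.60),
    10: (0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50, 0.55, 0.60),
}


def classify_dgp(gamma: float, tau2: float) -> str:
    """Classify a (gamma, tau2) pair into one of the four heterogeneity types.

    Equality with ``gamma == 1`` and ``tau2 == 0`` is tested exactly: grid
    values are assigned constants, never the result of computation.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    if tau2 < 0:
        raise ValueError(f"tau2 must be non-negative, got {tau2}")
    if gamma == 1.0:
        return "FE" if tau2 == 0.0 else "RE"
    return "UWLS_FE" if tau2 == 0.0 else "UWLS_RE"


def sigma_profile(n_studies: int) -> np.ndarray:
    """Within-study sampling SDs for a meta-analysis of ``n_studies`` studies.

    For N in {3, 5, 10} this is the calibrated table above.  For the
    sample-size sweep (N a multiple of 10 above 10) the N = 10 profile is
    tiled N/10 times, preserving its empirical dispersion shape.
    """
    if n_studies in _SIGMA_TABLE:
        return np.asarray(_SIGMA_TABLE[n_studies], dtype=float)
    if n_studies > 10 and n_studies % 10 == 0:
        return np.tile(np.asarray(_SIGMA_TABLE[10], dtype=float), n_studies // 10)
    raise ValueError(
        "sigma_profile is defined for N in {3, 5, 10} or positive multiples "
        f"of 10; got N={n_studies}"
    )


@dataclass(frozen=True)
class DGPSpec:
    """One simulated-world configuration.

    Attributes
    ----------
    dgp_id
        Stable integer identifier (position in the canonical grid order).
    mu, gamma, tau2, n_studies
        The four design parameters.
    sigmas
        Within-study sampling SDs, length ``n_studies``.
    dgp_type
        Heterogeneity type implied by (gamma, tau2).
    """

    dgp_id: int
    mu: float
    gamma: float
    tau2: float
    n_studies: int
    sigmas: tuple[float, ...]
    dgp_type: str

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be a positive integer")
        if len(self.sigmas) != self.n_studies:
            raise ValueError("len(sigmas) must equal n_studies")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("all sigmas must be strictly positive")
        expected = classify_dgp(self.gamma, self.tau2)
        if self.dgp_type != expected:
            raise ValueError(
                f"dgp_type {self.dgp_type!r} inconsistent with "
                f"(gamma={self.gamma}, tau2={self.tau2}); expected {expected!r}"
            )


@dataclass
class MetaDataset:
    """One meta-analysis: paired effect estimates and reported sampling SDs.

    The random-effect and sampling-error components exist only transiently
    inside the simulator; a dataset stores what an analyst would observe.
    """

    effects: np.ndarray
    sigmas: np.ndarray
    provenance: Optional[DGPSpec] = None

    def __post_init__(self) -> None:
        self.effects = np.atleast_1d(np.asarray(self.effects, dtype=float))
        self.sigmas = np.atleast_1d(np.asarray(self.sigmas, dtype=float))
        if self.effects.shape != self.sigmas.shape or self.effects.ndim != 1:
            raise ValueError("effects and sigmas must be 1-D vectors of equal length")
        if self.effects.size < 1:
            raise ValueError("a meta-analysis needs at least one study")
        if np.any(self.sigmas <= 0):
            raise ValueError("all sigmas must be strictly positive")

    @property
    def n_studies(self) -> int:
        return int(self.effects.size)


def build_parameter_grid() -> list[DGPSpec]:
    """The canonical 108-configuration factorial grid, in a fixed order.

    Iteration order is the Cartesian product mu x gamma x tau2 x N with the
    value tuples above; ``dgp_id`` is the position in that order, so two
    calls always return identical sequences.
    """
    specs = []
    for i, (mu, gamma, tau2, n) in enumerate(
        product(MU_VALUES, GAMMA_VALUES, TAU2_VALUES, N_VALUES)
    ):
        specs.append(
            DGPSpec(
                dgp_id=i,
                mu=mu,
                gamma=gamma,
                tau2=tau2,
                n_studies=n,
                sigmas=tuple(sigma_profile(n)),
                dgp_type=classify_dgp(gamma, tau2),
            )
        )
    return specs


def build_sweep_grid(n_studies: int) -> list[DGPSpec]:
    """The 36 (mu, gamma, tau2) combinations instantiated at one sample size.

    Used by the sample-size sweep: the heterogeneity structure of the main
    grid is kept while N varies from 3 to thousands of studies.
    """
    sigmas = tuple(sigma_profile(n_studies))
    specs = []
    for i, (mu, gamma, tau2) in enumerate(
        product(MU_VALUES, GAMMA_VALUES, TAU2_VALUES)
    ):
        specs.append(
            DGPSpec(
                dgp_id=i,
                mu=mu,
                gamma=gamma,
                tau2=tau2,
                n_studies=n_studies,
                sigmas=sigmas,
                dgp_type=classify_dgp(gamma, tau2),
            )
        )
    return specs


def substream(master_seed: int, *key: int) -> np.random.Generator:
    """Independent random stream for one (experiment, dgp, replicate) cell.

    Streams are keyed, never sequential, so results are reproducible and
    independent of execution order (and hence of any parallel scheduling).
    """
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=tuple(key)))


def simulate_dataset(spec: DGPSpec, rng: np.random.Generator) -> MetaDataset:
    """Draw one meta-analysis dataset from a DGP configuration.

    y_i = mu + u_i + eps_i with u_i ~ N(0, gamma*tau2) and
    eps_i ~ N(0, gamma*sigma_i^2), drawn independently per study.  The
    returned ``sigmas`` are the spec's unscaled values: estimators never see
    the latent distortion ``gamma``.
    """
    sigmas = np.asarray(spec.sigmas, dtype=float)
    u = rng.normal(0.0, np.sqrt(spec.gamma * spec.tau2), size=spec.n_studies)
    eps = rng.normal(0.0, np.sqrt(spec.gamma) * sigmas)
    effects = spec.mu + u + eps
    return MetaDataset(effects=effects, sigmas=sigmas, provenance=spec)


def grid_to_frame(grid: Sequence[DGPSpec]):
    """Tabular view of a grid (dgp_id, mu, gamma, tau2, n_studies, dgp_type)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "dgp_id": [s.dgp_id for s in grid],
            "mu": [s.mu for s in grid],
            "gamma": [s.gamma for s in grid],
            "tau2": [s.tau2 for s in grid],
            "n_studies": [s.n_studies for s in grid],
            "dgp_type": [s.dgp_type for s in grid],
        }
    )
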
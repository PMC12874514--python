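"""The four meta-analytic estimators: FE, RE (ML), UWLS-FE, UWLS-RE.

All four model the observed effect of study *i* as ``y_i = mu + u_i + eps_i``
and differ only in the assumed variance structure:

==========  =================================  =========================
model       Var(y_i)                           free parameters (k)
==========  =================================  =========================
FE          sigma_i^2                          mu                    (1)
RE          sigma_i^2 + tau2                   mu, tau2              (2)
UWLS-FE     gamma * sigma_i^2                  mu, gamma             (2)
UWLS-RE     gamma * (sigma_i^2 + tau2)         mu, tau2, gamma       (3)
==========  =================================  =========================

Point-estimate identities that hold to machine precision (and are enforced
by tests): the multiplicative scale ``gamma`` cancels from the weighted
mean, so UWLS-FE shares the FE point estimate and UWLS-RE shares the RE
point estimate.  What changes is the standard error: UWLS rescales it by
``sqrt(gamma_hat)`` where ``gamma_hat`` equals the heterogeneity statistic
H^2 = Q/(N-1) (Cochran's Q over its degrees of freedom).  ``gamma_hat`` is
deliberately *not* truncated at 1 — values below 1 ("excessive
homogeneity") shrink the standard error, which is the behaviour under
study.

Likelihood convention
---------------------
Each fit reports the Gaussian log-likelihood of its own variance model
maximized over its free parameters.  For the UWLS models the scale
parameter enters the likelihood at its ML value (Q/N), while the *reported*
``gamma_hat`` uses the unbiased-flavoured Q/(N-1) so that it coincides with
H^2.  This keeps AIC/BIC comparisons likelihood-coherent while preserving
the conventional H^2 reading of the scale estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .dgp import MetaDataset

__all__ = [
    "MODELS",
    "GAMMA_FLOOR",
    "FitResult",
    "fit_fe",
    "fit_re_ml",
    "fit_uwls_fe",
    "fit_uwls_re",
    "fit_all",
    "confidence_interval",
]

MODELS: tuple[str, ...] = ("FE", "RE", "UWLS_FE", "UWLS_RE")

# Lower bound for the multiplicative scale estimate; guards log(0) when all
# effects coincide.  No upper truncation: gamma_hat < 1 is meaningful.
GAMMA_FLOOR: float = 1e-12

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class FitResult:
    """One estimator's output on one meta-analysis.

    Attributes
    ----------
    model
        One of ``MODELS``.
    mu_hat, se_mu
        Pooled effect estimate and its standard error.
    tau2_hat
        Additive between-study variance estimate (0 for FE / UWLS-FE).
    gamma_hat
        Multiplicative variance scale estimate (1 for FE / RE).
    loglik
        Maximized Gaussian log-likelihood of the model's own variance
        structure, with scale parameters at their ML (divide-by-N) values.
    n_params
        Number of free parameters k used by AIC/BIC.
    ci_low, ci_high
        Normal-quantile confidence interval at the fit's level.
    """

    model: str
    mu_hat: float
    se_mu: float
    tau2_hat: float
    gamma_hat: float
    loglik: float
    n_params: int
    ci_low: float
    ci_high: float


def _interval(mu_hat: float, se_mu: float, level: float) -> tuple[float, float]:
    z = norm.ppf(0.5 + level / 2.0)
    return mu_hat - z * se_mu, mu_hat + z * se_mu


def confidence_interval(fit: FitResult, level: float = 0.95) -> tuple[float, float]:
    """Normal-quantile interval ``mu_hat +- z_{(1+level)/2} * se_mu``."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie strictly between 0 and 1, got {level}")
    return _interval(fit.mu_hat, fit.se_mu, level)


def fit_fe(data: MetaDataset, level: float = 0.95) -> FitResult:
    """Fixed-effects fit: inverse-variance weighted mean.

    Weights w_i = 1/sigma_i^2; mu_hat = sum(w y)/sum(w) with variance
    1/sum(w).  The log-likelihood is the Gaussian density of the FE variance
    model (no free scale), so no plug-in is needed.
    """
    y = data.effects
    s2 = data.sigmas**2
    w = 1.0 / s2
    sw = w.sum()
    mu_hat = float((w * y).sum() / sw)
    se_mu = float(sw**-0.5)
    r = y - mu_hat
    loglik = float(-0.5 * np.sum(_LOG_2PI + np.log(s2) + r * r / s2))
    lo, hi = _interval(mu_hat, se_mu, level)
    return FitResult("FE", mu_hat, se_mu, 0.0, 1.0, loglik, 1, lo, hi)


def _re_profile_nll(tau2: float, y: np.ndarray, s2: np.ndarray) -> float:
    """Negative profile log-likelihood of the RE model at fixed tau2.

    For fixed tau2 the ML mu is the weighted mean with w_i = 1/(s2_i+tau2),
    so the 2-D problem reduces to a 1-D search over tau2 >= 0.
    """
    v = s2 + tau2
    w = 1.0 / v
    mu = (w * y).sum() / w.sum()
    r = y - mu
    return float(0.5 * np.sum(_LOG_2PI + np.log(v) + r * r / v))


def fit_re_ml(data: MetaDataset, level: float = 0.95) -> FitResult:
    """Random-effects fit by maximum likelihood.

    (mu_hat, tau2_hat) jointly maximize the Gaussian likelihood with
    Var(y_i) = sigma_i^2 + tau2, via profile likelihood over tau2 on
    [0, max(10*var(y), 1)] (bounded Brent, xatol 1e-10).  The tau2 = 0
    boundary is always evaluated explicitly, which both handles the common
    boundary solution and guarantees loglik(RE) >= loglik(FE) exactly.
    """
    if data.n_studies < 2:
        raise ValueError("RE requires at least 2 studies (tau2 unidentifiable)")
    y = data.effects
    s2 = data.sigmas**2
    upper = max(10.0 * float(np.var(y, ddof=1)), 1.0)
    res = minimize_scalar(
        _re_profile_nll,
        bounds=(0.0, upper),
        args=(y, s2),
        method="bounded",
        options={"xatol": 1e-10},
    )
    tau2_hat = float(res.x)
    nll = float(res.fun)
    nll0 = _re_profile_nll(0.0, y, s2)
    if nll0 <= nll:
        tau2_hat, nll = 0.0, nll0
    v = s2 + tau2_hat
    w = 1.0 / v
    sw = w.sum()
    mu_hat = float((w * y).sum() / sw)
    se_mu = float(sw**-0.5)
    lo, hi = _interval(mu_hat, se_mu, level)
    return FitResult("RE", mu_hat, se_mu, tau2_hat, 1.0, -nll, 2, lo, hi)


def fit_uwls_fe(
    data: MetaDataset, level: float = 0.95, _fe: Optional[FitResult] = None
) -> FitResult:
    """Unrestricted WLS with a common effect: FE mean, rescaled uncertainty.

    The point estimate is the FE weighted mean (gamma cancels from the
    weights).  With Q = sum((y_i - mu_hat)^2 / sigma_i^2),

        gamma_hat = H^2 = Q/(N-1)      (floored at GAMMA_FLOOR, no cap at 1)
        se_mu     = sqrt(gamma_hat) * se_mu(FE)

    The log-likelihood uses the ML scale Q/N, for which the maximized value
    has the closed form  -(N/2)[log(2 pi) + log(Q/N) + 1] - sum(log sigma_i).
    """
    if data.n_studies < 2:
        raise ValueError("UWLS-FE requires at least 2 studies (gamma unidentifiable)")
    fe = _fe if _fe is not None else fit_fe(data, level)
    y = data.effects
    s2 = data.sigmas**2
    n = data.n_studies
    r = y - fe.mu_hat
    q = float(np.sum(r * r / s2))
    gamma_hat = max(q / (n - 1), GAMMA_FLOOR)
    se_mu = float(np.sqrt(gamma_hat) * fe.se_mu)
    gamma_ml = max(q / n, GAMMA_FLOOR)
    loglik = float(
        -0.5 * n * (_LOG_2PI + np.log(gamma_ml) + 1.0) - 0.5 * np.sum(np.log(s2))
    )
    lo, hi = _interval(fe.mu_hat, se_mu, level)
    return FitResult("UWLS_FE", fe.mu_hat, se_mu, 0.0, gamma_hat, loglik, 2, lo, hi)


def fit_uwls_re(
    data: MetaDataset, level: float = 0.95, _re: Optional[FitResult] = None
) -> FitResult:
    """Unrestricted WLS on the random-effects variance structure (two-step).

    Step 1 estimates tau2 by RE maximum likelihood.  Step 2 treats tau2 as
    fixed, forms weights v_i = 1/(sigma_i^2 + tau2_hat), and estimates the
    common effect (identical to the RE point estimate) plus a multiplicative
    scale on the combined variance:

        Q* = sum(v_i (y_i - mu_hat)^2),  gamma_hat = Q*/(N-1),
        se_mu = sqrt(gamma_hat) / sqrt(sum(v_i)).

    Because tau2 is fixed in step 2 this is not joint ML; the reported
    likelihood plugs the step-2 ML scale Q*/N into the three-parameter
    variance model, and k = 3 free parameters are charged to AIC/BIC.
    """
    if data.n_studies < 2:
        raise ValueError("UWLS-RE requires at least 2 studies")
    re = _re if _re is not None else fit_re_ml(data, level)
    y = data.effects
    s2 = data.sigmas**2
    n = data.n_studies
    v = s2 + re.tau2_hat
    w = 1.0 / v
    sw = w.sum()
    mu_hat = float((w * y).sum() / sw)
    r = y - mu_hat
    q_star = float(np.sum(w * r * r))
    gamma_hat = max(q_star / (n - 1), GAMMA_FLOOR)
    se_mu = float(np.sqrt(gamma_hat) * sw**-0.5)
    gamma_ml = max(q_star / n, GAMMA_FLOOR)
    loglik = float(
        -0.5 * n * (_LOG_2PI + np.log(gamma_ml) + 1.0) - 0.5 * np.sum(np.log(v))
    )
    lo, hi = _interval(mu_hat, se_mu, level)
    return FitResult(
        "UWLS_RE", mu_hat, se_mu, float(re.tau2_hat), gamma_hat, loglik, 3, lo, hi
    )


def fit_all(data: MetaDataset, level: float = 0.95) -> dict[str, FitResult]:
    """Fit all four models, sharing the FE and RE solutions with their
    UWLS counterparts (which reuse the same point estimates)."""
    fe = fit_fe(data, level)
    re = fit_re_ml(data, level)
    return {
        "FE": fe,
        "RE": re,
        "UWLS_FE": fit_uwls_fe(data, level, _fe=fe),
        "UWLS_RE": fit_uwls_re(data, level, _re=re),
    }
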
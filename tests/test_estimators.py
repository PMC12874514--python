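"""Estimator correctness: closed forms, ML oracle agreement, identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from metaselect import (
    MetaDataset,
    confidence_interval,
    fit_all,
    fit_fe,
    fit_re_ml,
    fit_uwls_fe,
    fit_uwls_re,
)
from metaselect.estimators import GAMMA_FLOOR, _re_profile_nll

from conftest import random_dataset


def _datasets(seed: int, count: int):
    rng = np.random.default_rng(seed)
    return [random_dataset(rng) for _ in range(count)]


class TestFE:
    def test_toy_weighted_mean(self, toy3):
        # independent arithmetic: w = 1/sigma^2
        w = 1.0 / np.array([0.3, 0.4, 0.5]) ** 2
        y = np.array([0.1, 0.2, 0.3])
        fit = fit_fe(toy3)
        assert fit.mu_hat == pytest.approx(float(w @ y / w.sum()), abs=1e-12)
        assert fit.mu_hat == pytest.approx(0.16671, abs=5e-6)
        assert fit.se_mu == pytest.approx(w.sum() ** -0.5, abs=1e-12)
        assert fit.se_mu == pytest.approx(0.21637, abs=5e-6)
        assert fit.tau2_hat == 0.0 and fit.gamma_hat == 1.0 and fit.n_params == 1

    def test_loglik_is_direct_density_sum(self, toy3):
        fit = fit_fe(toy3)
        direct = norm.logpdf(toy3.effects, fit.mu_hat, toy3.sigmas).sum()
        assert fit.loglik == pytest.approx(direct, abs=1e-12)

    def test_equal_sigmas_reduce_to_arithmetic_mean(self):
        data = MetaDataset([0.1, 0.5, 0.9], [0.4, 0.4, 0.4])
        assert fit_fe(data).mu_hat == pytest.approx(0.5, abs=1e-12)

    def test_single_study(self):
        fit = fit_fe(MetaDataset([0.7], [0.25]))
        assert fit.mu_hat == pytest.approx(0.7)
        assert fit.se_mu == pytest.approx(0.25)


class TestREML:
    def test_matches_metafor_ml_boundary(self, boundary5):
        # frozen reference: R metafor 4.8-0, rma(yi, sei, method="ML")
        fit = fit_re_ml(boundary5)
        assert fit.mu_hat == pytest.approx(0.1661842849, abs=1e-6)
        assert fit.se_mu == pytest.approx(0.1426551103, abs=1e-6)
        assert fit.tau2_hat == pytest.approx(0.0, abs=1e-8)
        assert fit.loglik == pytest.approx(-0.2359731898, abs=1e-8)

    def test_matches_metafor_ml_interior(self, dispersed5):
        # frozen reference: R metafor 4.8-0, rma(yi, sei, method="ML")
        fit = fit_re_ml(dispersed5)
        assert fit.mu_hat == pytest.approx(0.4575392427, abs=1e-6)
        assert fit.se_mu == pytest.approx(0.2434797344, abs=1e-5)
        assert fit.tau2_hat == pytest.approx(0.1538434930, abs=1e-5)
        assert fit.loglik == pytest.approx(-4.0399686086, abs=1e-8)

    def test_agrees_with_zoomed_grid_search(self, dispersed5):
        """Brute-force profile-likelihood scan reproduces the optimizer."""
        y, s2 = dispersed5.effects, dispersed5.sigmas**2
        lo, hi = 0.0, 4.0 * float(np.var(y, ddof=1))
        best = None
        for _ in range(4):  # iterative zoom: final resolution ~ (hi-lo)/500^4
            taus = np.linspace(lo, hi, 501)
            nlls = [_re_profile_nll(t, y, s2) for t in taus]
            k = int(np.argmin(nlls))
            best = taus[k]
            step = taus[1] - taus[0]
            lo, hi = max(0.0, best - step), best + step
        fit = fit_re_ml(dispersed5)
        assert fit.tau2_hat == pytest.approx(best, abs=1e-4)
        w = 1.0 / (s2 + best)
        assert fit.mu_hat == pytest.approx(float(w @ y / w.sum()), abs=1e-4)

    def test_identical_effects_give_zero_tau2(self):
        data = MetaDataset([0.4, 0.4, 0.4], [0.3, 0.4, 0.5])
        fit = fit_re_ml(data)
        assert fit.tau2_hat == 0.0
        assert fit.mu_hat == pytest.approx(fit_fe(data).mu_hat, abs=1e-12)

    def test_requires_two_studies(self):
        with pytest.raises(ValueError):
            fit_re_ml(MetaDataset([0.1], [0.2]))

    @pytest.mark.parametrize("seed", range(5))
    def test_loglik_dominates_fe(self, seed):
        # FE is the tau2 = 0 boundary of RE, so RE's ML can never be worse
        for data in _datasets(seed, 20):
            assert fit_re_ml(data).loglik >= fit_fe(data).loglik


class TestUWLSFE:
    def test_toy_q_gamma_se(self, toy3):
        fe = fit_fe(toy3)
        r = toy3.effects - fe.mu_hat
        q = float(np.sum(r**2 / toy3.sigmas**2))
        fit = fit_uwls_fe(toy3)
        assert q == pytest.approx(0.12744, abs=5e-6)
        assert fit.gamma_hat == pytest.approx(q / 2, abs=1e-12)
        assert fit.gamma_hat == pytest.approx(0.06372, abs=5e-6)
        assert fit.se_mu == pytest.approx(np.sqrt(q / 2) * fe.se_mu, abs=1e-12)
        assert fit.se_mu == pytest.approx(0.05462, abs=5e-6)
        assert fit.n_params == 2

    def test_point_estimate_identical_to_fe(self):
        for data in _datasets(101, 30):
            assert fit_uwls_fe(data).mu_hat == fit_fe(data).mu_hat

    def test_degenerate_homogeneity_hits_floor(self):
        data = MetaDataset([0.4, 0.4, 0.4], [0.3, 0.4, 0.5])
        fit = fit_uwls_fe(data)
        assert fit.gamma_hat == GAMMA_FLOOR
        assert fit.se_mu == pytest.approx(0.0, abs=1e-5)

    def test_requires_two_studies(self):
        with pytest.raises(ValueError):
            fit_uwls_fe(MetaDataset([0.1], [0.2]))


class TestUWLSRE:
    def test_point_estimate_identical_to_re(self):
        for data in _datasets(202, 30):
            assert fit_uwls_re(data).mu_hat == fit_re_ml(data).mu_hat

    def test_collapses_to_uwls_fe_when_tau2_zero(self, boundary5):
        re = fit_re_ml(boundary5)
        assert re.tau2_hat == 0.0
        ure = fit_uwls_re(boundary5)
        ufe = fit_uwls_fe(boundary5)
        assert ure.gamma_hat == ufe.gamma_hat
        assert ure.se_mu == ufe.se_mu

    def test_q_star_hand_computed_from_step1_tau2(self, dispersed5):
        re = fit_re_ml(dispersed5)
        v = 1.0 / (dispersed5.sigmas**2 + re.tau2_hat)
        mu = float(v @ dispersed5.effects / v.sum())
        q_star = float(np.sum(v * (dispersed5.effects - mu) ** 2))
        fit = fit_uwls_re(dispersed5)
        assert fit.gamma_hat == pytest.approx(q_star / 4, abs=1e-10)
        assert fit.se_mu == pytest.approx(
            np.sqrt(q_star / 4) * v.sum() ** -0.5, abs=1e-10
        )
        assert fit.n_params == 3


class TestConfidenceInterval:
    def test_unit_se(self):
        fit = fit_fe(MetaDataset([0.0], [1.0]))
        lo, hi = confidence_interval(fit, 0.95)
        assert lo == pytest.approx(-1.959964, abs=1e-5)
        assert hi == pytest.approx(+1.959964, abs=1e-5)

    def test_half_width_scales_with_quantile(self, toy3):
        fit = fit_fe(toy3)
        lo, hi = confidence_interval(fit, 0.5)
        assert (hi - lo) / 2 == pytest.approx(0.674490 * fit.se_mu, abs=1e-6)

    def test_zero_width_when_se_zero(self):
        data = MetaDataset([0.4, 0.4, 0.4], [0.3, 0.4, 0.5])
        fit = fit_uwls_fe(data)
        lo, hi = confidence_interval(fit, 0.95)
        assert lo == pytest.approx(fit.mu_hat, abs=1e-5)
        assert hi == pytest.approx(fit.mu_hat, abs=1e-5)

    @pytest.mark.parametrize("level", [0.0, 1.0, -0.5, 1.5])
    def test_invalid_level(self, toy3, level):
        with pytest.raises(ValueError):
            confidence_interval(fit_fe(toy3), level)


class TestCrossCheckStatsmodels:
    def test_fe_pooled_estimate_matches_statsmodels(self, dispersed5):
        from statsmodels.stats.meta_analysis import combine_effects

        res = combine_effects(
            dispersed5.effects, dispersed5.sigmas**2, method_re="dl"
        )
        fit = fit_fe(dispersed5)
        assert fit.mu_hat == pytest.approx(res.mean_effect_fe, abs=1e-10)
        assert fit.se_mu == pytest.approx(res.sd_eff_w_fe, abs=1e-10)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(0, 10_000), st.integers(2, 12))
def test_fit_invariants_hold_on_random_datasets(seed, n):
    """Structural invariants of every fit on arbitrary inputs."""
    data = random_dataset(np.random.default_rng(seed), n)
    fits = fit_all(data)
    assert fits["UWLS_FE"].mu_hat == fits["FE"].mu_hat
    assert fits["UWLS_RE"].mu_hat == fits["RE"].mu_hat
    assert fits["RE"].loglik >= fits["FE"].loglik
    for f in fits.values():
        assert f.ci_low <= f.mu_hat <= f.ci_high
        assert f.se_mu >= 0.0
        assert f.tau2_hat >= 0.0
        assert f.gamma_hat > 0.0
    # se(UWLS-FE) = sqrt(H^2) * se(FE) exactly
    assert fits["UWLS_FE"].se_mu == pytest.approx(
        np.sqrt(fits["UWLS_FE"].gamma_hat) * fits["FE"].se_mu, rel=1e-12
    )


class TestParameterRecovery:
    """With many studies the scale and heterogeneity estimates are consistent."""

    def test_gamma_recovery_under_multiplicative_dgp(self):
        # gamma=1.5, tau2=0: H^2 estimates gamma; Q/gamma ~ chi2(N-1)
        from metaselect.dgp import DGPSpec, simulate_dataset, substream, sigma_profile

        n, reps, gamma = 1000, 500, 1.5
        spec = DGPSpec(0, 0.5, gamma, 0.0, n, tuple(sigma_profile(n)), "UWLS_FE")
        est = np.empty(reps)
        for i in range(reps):
            data = simulate_dataset(spec, substream(31, 9, 0, i))
            est[i] = fit_uwls_fe(data).gamma_hat
        mc_se = est.std(ddof=1) / np.sqrt(reps)
        assert abs(est.mean() - gamma) < 3 * mc_se

    def test_tau2_recovery_under_additive_dgp(self):
        # gamma=1, tau2=0.10: RE ML tau2 is consistent
        from metaselect.dgp import DGPSpec, simulate_dataset, substream, sigma_profile

        n, reps, tau2 = 1000, 500, 0.10
        spec = DGPSpec(0, 0.5, 1.0, tau2, n, tuple(sigma_profile(n)), "RE")
        est = np.empty(reps)
        for i in range(reps):
            data = simulate_dataset(spec, substream(37, 9, 1, i))
            est[i] = fit_re_ml(data).tau2_hat
        mc_se = est.std(ddof=1) / np.sqrt(reps)
        assert abs(est.mean() - tau2) < 3 * mc_se
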
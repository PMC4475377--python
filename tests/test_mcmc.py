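"""Sampler correctness: conjugate Gibbs, MH against quadrature, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from treevigor import JointData, McmcConfig, run_chain, sample_sigma2
from treevigor.core import PARAM_NAMES
from treevigor.mortality import default_basis

RNG = lambda s: np.random.default_rng(s)


class TestGibbsSigma:
    def test_prior_draw_moments(self):
        """With no residuals the draws follow the InverseGamma(3, 2) prior
        whose mean is b/(a-1) = 1."""
        rng = RNG(0)
        draws = np.array([sample_sigma2(rng, 3.0, 2.0) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(1.0, abs=0.02)
        # distributional check on stable summaries (the variance estimator
        # of an inverse gamma with a = 3 is itself heavy-tailed)
        from scipy.stats import invgamma
        for p in (0.25, 0.5, 0.75):
            assert np.quantile(draws, p) == pytest.approx(
                invgamma.ppf(p, 3.0, scale=2.0), rel=0.02)

    def test_zero_residuals_shift_shape_only(self):
        """Ten exactly-zero residuals give InverseGamma(a0+5, b0)."""
        rng = RNG(1)
        a0, b0, n = 3.0, 2.0, 10
        draws = np.array([sample_sigma2(rng, a0, b0, np.zeros(n)) for _ in range(100_000)])
        a, b = a0 + n / 2, b0
        assert draws.mean() == pytest.approx(b / (a - 1), rel=0.02)

    def test_posterior_concentration(self):
        """With 10^4 residuals at sd 0.5 the posterior sd concentrates."""
        rng = RNG(2)
        resid = rng.normal(0, 0.5, size=10_000)
        sig = np.sqrt([sample_sigma2(rng, 0.001, 0.001, resid) for _ in range(2_000)])
        assert 0.49 < sig.mean() < 0.51


def toy_logistic_data(n=20, seed=7, beta_true=-2.0):
    """Mortality-only data with a single active predictor (wood density):
    the 1-parameter logistic toy whose posterior is computable by
    quadrature."""
    rng = RNG(seed)
    wd = np.linspace(0.3, 0.9, n)
    died = rng.random(n) < expit(beta_true * wd)
    zeros = np.zeros(n)
    return JointData(
        g_y=np.zeros(0), g_dbh=np.zeros(0), g_dbh95=np.zeros(0),
        g_wd=np.zeros(0), g_hmax=np.zeros(0), g_d13c=np.zeros(0),
        m_vidx=np.full(n, -1, dtype=np.int64), m_x=np.ones(n),
        m_died=died,
        m_cols={"beta1": zeros, "beta2": zeros, "beta3": zeros,
                "beta4": zeros, "beta5": wd, "beta6": zeros},
        basis=default_basis(), width_link="linear",
        first_interval_vigor="zero", interval_years=10.0,
        n_trees=n, n_clamped=0,
        g_frame=pd.DataFrame(), m_frame=pd.DataFrame(),
    )


def toy_quadrature(data, prior_sd=10.0, grid=None):
    """Numerical posterior of the toy's single coefficient."""
    if grid is None:
        grid = np.linspace(-15.0, 8.0, 8001)
    wd = data.m_cols["beta5"]
    y = data.m_died.astype(float)
    eta = np.outer(grid, wd)
    ll = (y * -np.logaddexp(0, -eta) + (1 - y) * -np.logaddexp(0, eta)).sum(axis=1)
    lp = ll - 0.5 * grid**2 / prior_sd**2
    w = np.exp(lp - lp.max())
    w /= np.trapezoid(w, grid)
    mean = np.trapezoid(w * grid, grid)
    cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(grid))])
    cdf /= cdf[-1]
    return mean, grid, cdf


def toy_fixed():
    fixed = {n: 0.0 for n in PARAM_NAMES if n != "beta5"}
    fixed.update({"theta5": 1.0, "theta6": 1.0, "sigma": 0.5})
    return fixed


@pytest.fixture(scope="module")
def toy_chain():
    data = toy_logistic_data()
    cfg = McmcConfig(n_chains=1, n_iter_phase1=1000, n_iter_phase2=51_000,
                     burn_in=1000, thinning=1, fixed=toy_fixed())
    draws, state = run_chain(data, cfg, seed=123)
    return data, draws["beta5"].to_numpy(), state


class TestMetropolisAgainstQuadrature:
    def test_posterior_mean_within_two_percent(self, toy_chain):
        data, draws, _ = toy_chain
        mean, _, _ = toy_quadrature(data)
        assert draws.mean() == pytest.approx(mean, rel=0.02)

    def test_quantiles_match_quadrature(self, toy_chain):
        """Goodness of fit on 10 quantiles: each within 1% of the
        posterior's central 90% width."""
        data, draws, _ = toy_chain
        _, grid, cdf = toy_quadrature(data)
        probs = np.linspace(0.05, 0.95, 10)
        q_quad = np.interp(probs, cdf, grid)
        q_mcmc = np.quantile(draws, probs)
        width = np.interp(0.95, cdf, grid) - np.interp(0.05, cdf, grid)
        np.testing.assert_allclose(q_mcmc, q_quad, atol=0.01 * width)

    def test_near_identity_proposal_always_accepted(self):
        """A vanishingly small random-walk step has posterior ratio ~1 and
        is accepted essentially every time."""
        data = toy_logistic_data()
        cfg = McmcConfig(n_chains=1, n_iter_phase1=0, n_iter_phase2=400,
                         burn_in=1, thinning=1, proposal_sd=1e-12,
                         fixed=toy_fixed())
        _, state = run_chain(data, cfg, seed=3)
        rate = state.accepts["beta5"] / state.attempts["beta5"]
        assert rate > 0.999


class TestReproducibility:
    def test_identical_seed_gives_bitwise_identical_draws(self):
        data = toy_logistic_data()
        cfg = McmcConfig(n_chains=1, n_iter_phase1=200, n_iter_phase2=300,
                         burn_in=100, thinning=2, fixed=toy_fixed())
        d1, _ = run_chain(data, cfg, seed=11)
        d2, _ = run_chain(data, cfg, seed=11)
        pd.testing.assert_frame_equal(d1, d2)

    def test_selection_disabled_equals_plain_run(self):
        """An empty candidate list leaves the sweep identical to plain MH."""
        data = toy_logistic_data()
        cfg_a = McmcConfig(n_chains=1, n_iter_phase1=200, n_iter_phase2=300,
                           burn_in=100, thinning=2, fixed=toy_fixed(), select=())
        cfg_b = McmcConfig(n_chains=1, n_iter_phase1=200, n_iter_phase2=300,
                           burn_in=100, thinning=2, fixed=toy_fixed())
        d1, _ = run_chain(data, cfg_a, seed=5)
        d2, _ = run_chain(data, cfg_b, seed=5)
        pd.testing.assert_frame_equal(d1, d2)


class TestAdaptation:
    def test_acceptance_rates_land_in_target_band(self, medium_fit):
        """After phase-1 adaptation, every adapted parameter's phase-2
        acceptance rate sits in the configured band."""
        _, _, results = medium_fit
        lo, hi = results.config.target_accept
        for name, rate in results.acceptance.items():
            assert lo - 0.05 <= rate <= hi + 0.1, (name, rate)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            McmcConfig(burn_in=500, n_iter_phase2=400)
        with pytest.raises(ValueError):
            McmcConfig(thinning=0)
        with pytest.raises(ValueError):
            McmcConfig(select=("nonsense",))
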
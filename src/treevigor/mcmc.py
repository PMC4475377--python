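"""MH-within-Gibbs sampler with Kuo-Mallick indicator selection.

Parameters are sampled one at a time: Gaussian random-walk
Metropolis-Hastings for the growth coefficients theta1..theta6 and the
mortality coefficients beta0..beta6, and a conjugate inverse-gamma Gibbs
draw for the growth residual variance sigma^2 (theta7).  The sampler
exploits the likelihood's component structure: a mortality-coefficient
update recomputes only the Bernoulli component, while a growth-coefficient
update recomputes both, because the growth residuals propagate into the
mortality linear predictor through the vigor covariate.

Sampling runs in two phases.  During phase 1 the per-parameter proposal
scales adapt toward a target acceptance band; phase 2 runs with frozen
scales (preserving detailed balance), and only phase-2 draws after
burn-in, thinned, are retained.

Variable selection follows the Kuo-Mallick construction: each of the
eight candidate predictors carries a binary inclusion indicator gamma
multiplying its coefficient.  The indicator is drawn from its full
conditional (a Bernoulli comparing the likelihood with the term in and
out); while excluded, the coefficient evolves from its prior, so it can
re-enter.  The posterior mean of gamma is the predictor's inclusion
frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import (
    BETA_NAMES,
    CANDIDATE_PREDICTORS,
    PARAM_NAMES,
    THETA_NAMES,
    JointParams,
)
from .likelihood import JointData

logger = logging.getLogger("treevigor")

_POSITIVE_PARAMS = ("theta5", "theta6")


class InferenceError(RuntimeError):
    pass


@dataclass
class McmcConfig:
    """Sampler settings, priors and proposal scales.

    Defaults follow the two-phase design: 2000 adaptive iterations to
    reach the stationary region, then 3500 frozen iterations of which the
    first 1000 are burned and every 10th retained.  ``n_chains`` defaults
    to 4 for desk use (the full-scale design used 100 parallel chains).
    Priors: Normal(0, prior_coef_sd^2) on every coefficient (theta5 and
    theta6 truncated positive), InverseGamma(shape, rate) on sigma^2,
    independent Bernoulli(prior_inclusion) on each selection indicator.
    ``select`` lists the candidate predictors whose indicators are
    sampled; empty disables selection.  ``fixed`` pins parameters at given
    values (e.g. ``{"beta0": 0.0}`` for the no-vigor comparator model).
    """

    n_chains: int = 4
    n_iter_phase1: int = 2000
    n_iter_phase2: int = 3500
    burn_in: int = 1000
    thinning: int = 10
    proposal_sd: float = 0.1
    proposal_sd_overrides: Dict[str, float] = field(default_factory=dict)
    phase2_shrink: float = 1.0
    adapt_interval: int = 100
    adapt_factor: float = 0.5
    target_accept: Tuple[float, float] = (0.2, 0.5)
    prior_coef_sd: float = 10.0
    prior_sigma2_shape: float = 0.001
    prior_sigma2_rate: float = 0.001
    prior_inclusion: float = 0.5
    select: Tuple[str, ...] = ()
    fixed: Dict[str, float] = field(default_factory=dict)
    gamma_init: Dict[str, int] = field(default_factory=lambda: {"beta4": 0})
    init_box: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    max_init_retries: int = 100

    def __post_init__(self):
        if self.burn_in >= self.n_iter_phase2:
            raise ValueError("burn_in must be smaller than n_iter_phase2")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.proposal_sd <= 0 or any(v <= 0 for v in self.proposal_sd_overrides.values()):
            raise ValueError("proposal sds must be positive")
        for name in self.select:
            if name not in CANDIDATE_PREDICTORS:
                raise ValueError(f"unknown candidate predictor {name!r}")

    def initial_gamma(self) -> Dict[str, int]:
        gamma = {name: 1 for name in CANDIDATE_PREDICTORS}
        gamma.update(self.gamma_init)
        for name in self.select:  # candidates under selection start included
            gamma[name] = 1
        return gamma

    def initial_box(self, name: str) -> Tuple[float, float]:
        if name in self.init_box:
            return self.init_box[name]
        if name == "theta5":
            return (0.3, 1.5)
        if name == "theta6":
            return (1.0, 8.0)
        if name == "sigma":
            return (0.2, 2.0)
        return (-3.0, 3.0)


@dataclass
class ChainState:
    """Current position of one chain plus its likelihood caches."""

    params: JointParams
    mu: np.ndarray
    resid: np.ndarray
    ssr: float
    vigor: np.ndarray
    eta_static: np.ndarray
    eta: np.ndarray
    ll_growth: float
    ll_mort: float
    proposal_sd: Dict[str, float]
    rng: np.random.Generator
    iteration: int = 0
    accepts: Dict[str, int] = field(default_factory=dict)
    attempts: Dict[str, int] = field(default_factory=dict)
    window_accepts: Dict[str, int] = field(default_factory=dict)
    window_attempts: Dict[str, int] = field(default_factory=dict)

    @property
    def loglik(self) -> float:
        return self.ll_growth + self.ll_mort


# ---------------------------------------------------------------------------
# cache (re)computation

def _gaussian_ll(n: int, ssr: float, sigma: float) -> float:
    return -0.5 * n * (np.log(2.0 * np.pi) + 2.0 * np.log(sigma)) - 0.5 * ssr / (sigma * sigma)


def _growth_caches(data: JointData, params: JointParams):
    mu = data.growth_mu(params.theta_eff())
    resid = data.g_y - mu
    ssr = float(resid @ resid)
    ll_g = _gaussian_ll(data.n_growth, ssr, params.sigma)
    return mu, resid, ssr, ll_g


def make_state(data: JointData, params: JointParams, rng: np.random.Generator,
               cfg: McmcConfig) -> ChainState:
    mu, resid, ssr, ll_g = _growth_caches(data, params)
    beta_eff = params.beta_eff()
    vigor = data.vigor_from_resid(resid)
    eta_static = data.eta_static(beta_eff, params.intercept)
    eta = eta_static + beta_eff[0] * vigor
    ll_m = data.mortality_loglik(eta)
    sds = {name: cfg.proposal_sd_overrides.get(name, cfg.proposal_sd)
           for name in PARAM_NAMES if name != "sigma"}
    return ChainState(params=params, mu=mu, resid=resid, ssr=ssr, vigor=vigor,
                      eta_static=eta_static, eta=eta, ll_growth=ll_g, ll_mort=ll_m,
                      proposal_sd=sds, rng=rng)


def _coef_logprior(value: float, sd: float) -> float:
    return -0.5 * value * value / (sd * sd)


# ---------------------------------------------------------------------------
# elementary updates

def mh_update_scalar(state: ChainState, name: str, data: JointData,
                     cfg: McmcConfig) -> None:
    """One random-walk MH update of a theta or beta coefficient, in place.

    A beta update touches only the mortality component (the scoping
    rule); a theta update recomputes growth residuals, vigor and the
    mortality component.  A coefficient whose inclusion indicator is
    currently 0 does not enter the likelihood and is refreshed from its
    prior (the Kuo-Mallick construction), without touching the
    acceptance counters used for adaptation.
    """
    params = state.params
    rng = state.rng
    if params.gamma.get(name, 1) == 0:
        setattr(params, name, rng.normal(0.0, cfg.prior_coef_sd))
        return

    cur = getattr(params, name)
    state.window_attempts[name] = state.window_attempts.get(name, 0) + 1
    state.attempts[name] = state.attempts.get(name, 0) + 1
    prop = cur + rng.normal(0.0, state.proposal_sd[name])
    if name in _POSITIVE_PARAMS and prop <= 0:
        return  # outside the truncated prior's support: reject

    dprior = _coef_logprior(prop, cfg.prior_coef_sd) - _coef_logprior(cur, cfg.prior_coef_sd)

    if name in THETA_NAMES:
        cand = params.replace(**{name: prop})
        try:
            mu, resid, ssr, ll_g = _growth_caches(data, cand)
        except Exception:
            return
        vigor = data.vigor_from_resid(resid)
        eta = state.eta_static + cand.beta_eff()[0] * vigor
        ll_m = data.mortality_loglik(eta)
        logr = (ll_g + ll_m) - (state.ll_growth + state.ll_mort) + dprior
        if np.isfinite(logr) and np.log(rng.random()) < logr:
            setattr(params, name, prop)
            state.mu, state.resid, state.ssr = mu, resid, ssr
            state.vigor, state.eta = vigor, eta
            state.ll_growth, state.ll_mort = ll_g, ll_m
            state.accepts[name] = state.accepts.get(name, 0) + 1
            state.window_accepts[name] = state.window_accepts.get(name, 0) + 1
        return

    # beta update: mortality component only
    delta = prop - cur
    if name == "beta0":
        eta = state.eta_static + prop * state.vigor
    else:
        eta = state.eta + delta * data.m_cols[name]
    ll_m = data.mortality_loglik(eta)
    logr = ll_m - state.ll_mort + dprior
    if np.isfinite(logr) and np.log(rng.random()) < logr:
        setattr(params, name, prop)
        if name != "beta0":
            state.eta_static = state.eta_static + delta * data.m_cols[name]
        state.eta = eta
        state.ll_mort = ll_m
        state.accepts[name] = state.accepts.get(name, 0) + 1
        state.window_accepts[name] = state.window_accepts.get(name, 0) + 1


def sample_sigma2(rng: np.random.Generator, shape0: float, rate0: float,
                  residuals: Optional[np.ndarray] = None) -> float:
    """Draw sigma^2 from its conjugate inverse-gamma full conditional.

    InverseGamma(shape0 + n/2, rate0 + SSR/2); with no residuals the draw
    comes from the prior.
    """
    if residuals is None or np.size(residuals) == 0:
        a, b = shape0, rate0
    else:
        r = np.asarray(residuals, dtype=float)
        a = shape0 + r.size / 2.0
        b = rate0 + 0.5 * float(r @ r)
    return b / rng.gamma(a)


def gibbs_update_sigma(state: ChainState, data: JointData, cfg: McmcConfig) -> None:
    """Conjugate Gibbs draw of sigma (theta7), in place."""
    if data.n_growth == 0:
        logger.info("no growth observations: sigma drawn from its prior")
        sigma2 = sample_sigma2(state.rng, cfg.prior_sigma2_shape, cfg.prior_sigma2_rate)
    else:
        a = cfg.prior_sigma2_shape + data.n_growth / 2.0
        b = cfg.prior_sigma2_rate + 0.5 * state.ssr
        sigma2 = b / state.rng.gamma(a)
    state.params.sigma = float(np.sqrt(sigma2))
    state.ll_growth = _gaussian_ll(data.n_growth, state.ssr, state.params.sigma)


def kuo_mallick_update(state: ChainState, name: str, data: JointData,
                       cfg: McmcConfig) -> None:
    """Gibbs draw of one inclusion indicator from its full conditional.

    The Bernoulli odds compare the likelihood with the predictor's term
    included (at the coefficient's current value) versus excluded; the
    indicator prior enters as its log-odds.
    """
    params = state.params
    prior_logodds = float(np.log(cfg.prior_inclusion) - np.log1p(-cfg.prior_inclusion))

    if name in THETA_NAMES:
        p_in = params.replace(gamma={**params.gamma, name: 1})
        p_out = params.replace(gamma={**params.gamma, name: 0})
        caches = {}
        for tag, cand in (("in", p_in), ("out", p_out)):
            mu, resid, ssr, ll_g = _growth_caches(data, cand)
            vigor = data.vigor_from_resid(resid)
            eta = state.eta_static + cand.beta_eff()[0] * vigor
            ll_m = data.mortality_loglik(eta)
            caches[tag] = (mu, resid, ssr, vigor, eta, ll_g, ll_m)
        d = (caches["in"][5] + caches["in"][6]) - (caches["out"][5] + caches["out"][6])
        g_new = int(state.rng.random() < expit(d + prior_logodds))
        params.gamma[name] = g_new
        mu, resid, ssr, vigor, eta, ll_g, ll_m = caches["in" if g_new else "out"]
        state.mu, state.resid, state.ssr = mu, resid, ssr
        state.vigor, state.eta = vigor, eta
        state.ll_growth, state.ll_mort = ll_g, ll_m
        return

    # mortality predictor: only the Bernoulli component changes
    col = data.m_cols[name]
    coef = getattr(params, name)
    g_cur = params.gamma[name]
    eta_in = state.eta if g_cur == 1 else state.eta + coef * col
    eta_out = state.eta - coef * col if g_cur == 1 else state.eta
    ll_in = data.mortality_loglik(eta_in) if g_cur == 0 else state.ll_mort
    ll_out = data.mortality_loglik(eta_out) if g_cur == 1 else state.ll_mort
    g_new = int(state.rng.random() < expit(ll_in - ll_out + prior_logodds))
    if g_new != g_cur:
        params.gamma[name] = g_new
        state.eta = eta_in if g_new else eta_out
        state.eta_static = state.eta - params.beta_eff()[0] * state.vigor
        state.ll_mort = ll_in if g_new else ll_out


# ---------------------------------------------------------------------------
# chain orchestration

def _sampled_names(cfg: McmcConfig, gamma: Dict[str, int]) -> Tuple[str, ...]:
    names = []
    for name in THETA_NAMES + BETA_NAMES:
        if name in cfg.fixed:
            continue
        if name in CANDIDATE_PREDICTORS and name not in cfg.select and gamma.get(name, 1) == 0:
            continue  # hard-excluded predictor: coefficient never enters
        names.append(name)
    return tuple(names)


def initialize_params(data: JointData, cfg: McmcConfig,
                      rng: np.random.Generator) -> JointParams:
    """Random start from the prior truncated to a sane box, retried until
    the joint likelihood is finite."""
    gamma = cfg.initial_gamma()
    for attempt in range(cfg.max_init_retries):
        kwargs = {}
        for name in PARAM_NAMES:
            lo, hi = cfg.initial_box(name)
            kwargs[name] = float(rng.uniform(lo, hi))
        for name, value in cfg.fixed.items():
            if name in PARAM_NAMES:
                kwargs[name] = float(value)
        params = JointParams(gamma=dict(gamma), **kwargs)
        ll = data.loglik(params)
        if np.isfinite(ll.total):
            return params
    raise InferenceError(
        f"no finite starting likelihood after {cfg.max_init_retries} retries; "
        "check the data or widen the init box")


def _adapt(state: ChainState, cfg: McmcConfig) -> None:
    lo, hi = cfg.target_accept
    for name, att in state.window_attempts.items():
        if att == 0:
            continue
        rate = state.window_accepts.get(name, 0) / att
        if rate < lo:
            state.proposal_sd[name] *= cfg.adapt_factor
        elif rate > hi:
            state.proposal_sd[name] /= cfg.adapt_factor
    state.window_accepts.clear()
    state.window_attempts.clear()


def _sweep(state: ChainState, data: JointData, cfg: McmcConfig,
           theta_names, beta_names) -> None:
    """One full update sweep: theta1..theta6, Gibbs sigma, beta0..beta6,
    then the selection indicators (fixed order for reproducibility)."""
    for name in theta_names:
        mh_update_scalar(state, name, data, cfg)
    if "sigma" not in cfg.fixed:
        gibbs_update_sigma(state, data, cfg)
    for name in beta_names:
        mh_update_scalar(state, name, data, cfg)
    for name in cfg.select:
        kuo_mallick_update(state, name, data, cfg)
    state.iteration += 1


def run_chain(data: JointData, cfg: McmcConfig, seed) -> Tuple[pd.DataFrame, ChainState]:
    """Run one chain; returns the retained thinned draws and final state."""
    rng = np.random.default_rng(seed)
    params = initialize_params(data, cfg, rng)
    state = make_state(data, params, rng, cfg)
    sampled = _sampled_names(cfg, params.gamma)
    theta_names = tuple(n for n in sampled if n in THETA_NAMES)
    beta_names = tuple(n for n in sampled if n in BETA_NAMES)
    # hard-excluded predictors never enter the likelihood: keep them out of the draws
    recorded = tuple(
        n for n in PARAM_NAMES
        if not (n in CANDIDATE_PREDICTORS and n not in cfg.select
                and params.gamma.get(n, 1) == 0))

    for it in range(cfg.n_iter_phase1):
        _sweep(state, data, cfg, theta_names, beta_names)
        if (it + 1) % cfg.adapt_interval == 0:
            _adapt(state, cfg)
    # freeze proposals for phase 2 (detailed balance)
    state.window_accepts.clear()
    state.window_attempts.clear()
    state.accepts.clear()
    state.attempts.clear()
    if cfg.phase2_shrink != 1.0:
        for name in state.proposal_sd:
            state.proposal_sd[name] *= cfg.phase2_shrink

    rows = []
    for it in range(cfg.n_iter_phase2):
        _sweep(state, data, cfg, theta_names, beta_names)
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thinning == 0:
            row = {n: getattr(state.params, n) for n in recorded}
            for name in cfg.select:
                row[f"gamma_{name}"] = state.params.gamma[name]
            row["loglik"] = state.loglik
            rows.append(row)
    return pd.DataFrame(rows), state


def posterior_summary(draws: pd.DataFrame, select: Sequence[str] = ()) -> pd.DataFrame:
    """Medians, 90% credibility intervals, inclusion frequencies and an
    effective-draw count for every sampled quantity."""
    names = [c for c in draws.columns if c in PARAM_NAMES]
    rows = {}
    for name in names:
        x = draws[name].to_numpy(dtype=float)
        rows[name] = {
            "median": float(np.median(x)),
            "q5": float(np.quantile(x, 0.05)),
            "q95": float(np.quantile(x, 0.95)),
            "inclusion_freq": np.nan,
            "n_draws": len(x),
            "ess": _ess(x),
        }
    for name in select:
        col = f"gamma_{name}"
        if col in draws.columns and name in rows:
            rows[name]["inclusion_freq"] = float(draws[col].mean())
    out = pd.DataFrame(rows).T
    out.index.name = "parameter"
    return out


def _ess(x: np.ndarray) -> float:
    try:
        import warnings
        import arviz as az
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(az.ess(np.asarray(x)[None, :]))
    except Exception:
        return float(len(x))


@dataclass
class McmcRun:
    """Pooled output of one or more chains."""

    draws: pd.DataFrame
    chains: Tuple[pd.DataFrame, ...]
    summary: pd.DataFrame
    acceptance: Dict[str, float]
    config: McmcConfig


def run_chains(data: JointData, cfg: McmcConfig, seed) -> McmcRun:
    """Run ``cfg.n_chains`` chains and pool retained draws.

    Chains use independent streams spawned from ``seed``; retained draws
    are pooled after per-chain burn-in and thinning.  Per-parameter
    phase-2 acceptance rates of the last chain are reported.
    """
    seqs = np.random.SeedSequence(seed).spawn(cfg.n_chains)
    chains = []
    state = None
    for seq in seqs:
        draws, state = run_chain(data, cfg, seq)
        draws = draws.copy()
        draws["chain"] = len(chains)
        chains.append(draws)
    pooled = pd.concat(chains, ignore_index=True)
    acc = {name: state.accepts.get(name, 0) / max(state.attempts.get(name, 1), 1)
           for name in state.attempts}
    summary = posterior_summary(pooled, cfg.select)
    return McmcRun(draws=pooled, chains=tuple(chains), summary=summary,
                   acceptance=acc, config=cfg)
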
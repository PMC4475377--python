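"""Model-comparison and calibration diagnostics.

Three surfaces: McFadden's (adjusted) pseudo-R2 on the Bernoulli
mortality component, a vigor-binned calibration table comparing observed
with resimulated death rates, and mortality response curves over the
ontogenetic stage for chosen trait profiles and vigor levels.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import JointParams, TRAIT_RANGES
from .likelihood import JointData
from .mortality import OntogenyBasis, default_basis, linear_predictor_arrays


def mcfadden_pseudo_r2(model_mortality_loglik: float, null_mortality_loglik: float,
                       k_params: int = 0) -> float:
    """McFadden's pseudo-R2, adjusted for the parameter count.

    1 - (lnL - k)/lnL0, with the Bernoulli mortality log-likelihoods of
    the fitted and of the null (intercept-only) model; k = 0 gives the
    unadjusted statistic.  Interpretable as the fraction of the null
    model's information recovered by the covariates.
    """
    if null_mortality_loglik >= 0:
        raise ValueError("null mortality log-likelihood must be negative")
    return 1.0 - (model_mortality_loglik - k_params) / null_mortality_loglik


def null_mortality_loglik(died) -> float:
    """Bernoulli log-likelihood of the intercept-only mortality model
    (every interval gets the empirical death rate)."""
    y = np.asarray(died, dtype=bool)
    n, d = y.size, int(y.sum())
    if n == 0:
        raise ValueError("no mortality observations")
    p = d / n
    if p in (0.0, 1.0):
        return 0.0
    return d * np.log(p) + (n - d) * np.log1p(-p)


def mortality_design(data: JointData, params: JointParams):
    """(vigor, eta, p, died, available) arrays at the given parameters."""
    mu = data.growth_mu(params.theta_eff())
    resid = data.g_y - mu
    beta_eff = params.beta_eff()
    vigor = data.vigor_from_resid(resid)
    eta = data.eta_static(beta_eff, params.intercept) + beta_eff[0] * vigor
    p = expit(eta)
    return vigor, eta, p, data.m_died, data.m_vidx >= 0


def vigor_calibration(data: JointData, params: JointParams, n_bins: int = 10,
                      n_sims: int = 100, seed=0) -> pd.DataFrame:
    """Vigor-binned observed vs. resimulated death rates.

    Intervals with an available vigor estimate are split into
    ``n_bins`` equal-count bins by vigor.  The observed death rate per
    bin is compared with ``n_sims`` Bernoulli resimulations under the
    model; the simulation 5%/95% quantiles give a 90% band.  Mortality
    being stochastic, a calibrated model has the observed rate inside the
    band and both rates decreasing from the lowest- to the
    highest-vigor bin when the vigor coefficient is negative.
    """
    vigor, eta, p, died, avail = mortality_design(data, params)
    vigor, p, died = vigor[avail], p[avail], died[avail]
    n = vigor.size
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} observations with vigor, got {n}")
    order = np.argsort(vigor, kind="mergesort")
    bins = np.array_split(order, n_bins)
    rng = np.random.default_rng(seed)
    sims = rng.random((n_sims, n)) < p  # shared draws across bins

    rows = []
    for b, idx in enumerate(bins):
        sim_rates = sims[:, idx].mean(axis=1)
        rows.append({
            "bin": b,
            "n": idx.size,
            "mean_vigor": float(vigor[idx].mean()),
            "observed_rate": float(died[idx].mean()),
            "predicted_rate": float(sim_rates.mean()),
            "predicted_q5": float(np.quantile(sim_rates, 0.05)),
            "predicted_q95": float(np.quantile(sim_rates, 0.95)),
        })
    return pd.DataFrame(rows)


def _default_trait_profiles() -> pd.DataFrame:
    mid = {name: 0.5 * (lo + hi) for name, (lo, hi) in TRAIT_RANGES.items()}
    rows = []
    for trait in ("hmax_dm", "wd", "tough"):
        lo, hi = TRAIT_RANGES[trait]
        for label, value in (("low", lo), ("mid", mid[trait]), ("high", hi)):
            prof = {"hmax_dm": mid["hmax_dm"], "wd": mid["wd"],
                    "tough": mid["tough"], "ortho": 0}
            prof[trait] = value
            rows.append({"trait": trait, "level": label, **prof})
    return pd.DataFrame(rows)


def mortality_response_surfaces(params: JointParams, *,
                                basis: Optional[OntogenyBasis] = None,
                                vigor_levels: Sequence[float] = (-1.0, 0.0, 1.0),
                                x_grid: Optional[np.ndarray] = None,
                                trait_profiles: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Death probability over ontogenetic stage x = D/DBH95.

    One curve per (trait profile, vigor level); by default each of the
    three continuous mortality traits is swept low/mid/high with the
    others at mid-range, for vigor -1, 0 and +1.  Returns a tidy frame
    with columns trait, level, vigor, x, p.
    """
    basis = basis or default_basis()
    if x_grid is None:
        x_grid = np.linspace(0.05, 1.2, 100)
    if trait_profiles is None:
        trait_profiles = _default_trait_profiles()
    beta = params.beta_eff()
    frames = []
    for _, prof in trait_profiles.iterrows():
        for v in vigor_levels:
            eta = linear_predictor_arrays(
                np.full_like(x_grid, float(v)), x_grid,
                prof["hmax_dm"], prof.get("ortho", 0), prof["wd"], prof["tough"],
                beta, basis, params.intercept)
            frames.append(pd.DataFrame({
                "trait": prof.get("trait", "profile"),
                "level": prof.get("level", ""),
                "vigor": float(v),
                "x": x_grid,
                "p": expit(eta),
            }))
    return pd.concat(frames, ignore_index=True)
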
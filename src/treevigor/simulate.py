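"""Forward census simulator for a Paracou-like tree community.

Generates a trait table and a longitudinal census from known joint
parameters so that inference can be validated by parameter recovery: the
community has no distributable field data, so simulation under the model
is the only route to a ground truth.  Defaults emulate the study design
the model was built for: 17,151 trees >= 10 cm DBH, censused every 10
years over 20 years (3 censuses, 2 intervals), species traits spanning
the community trait ranges, growth from the hump-shaped log-growth model
with additive individual noise and mortality from the vigor-dependent
logistic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import json
import numpy as np
import pandas as pd
from scipy.special import expit

from .core import (
    CANDIDATE_PREDICTORS,
    TRAIT_RANGES,
    CensusTable,
    JointParams,
    census_from_frame,
    write_census,
    write_traits,
)
from .growth import expected_log_growth
from .likelihood import FIRST_INTERVAL_MODES
from .mortality import default_basis, linear_predictor_arrays
from .units import m_to_cm

VIGOR_MODES = ("iid", "per_tree", "ar1")


def reference_params() -> JointParams:
    """Default generating parameter vector.

    Community-level posterior medians for a Guianan lowland forest
    (growth: theta1..theta6; mortality: beta0..beta6 with the stem
    orientation term excluded by selection), with the growth residual sd
    set to 0.5 on the log(AGR+1) scale.
    """
    gamma = {name: 1 for name in CANDIDATE_PREDICTORS}
    gamma["beta4"] = 0
    return JointParams(
        theta1=2.43, theta2=-0.384, theta3=0.0318, theta4=-0.403,
        theta5=0.767, theta6=4.81, sigma=0.5,
        beta0=-0.403, beta1=0.140, beta2=0.502, beta3=-0.414,
        beta4=0.0, beta5=-0.951, beta6=-0.327,
        gamma=gamma,
    )


@dataclass
class SimConfig:
    """Study-design settings of the forward simulator.

    Trait ranges default to the observed community ranges (uniform
    sampling; stem orientation Bernoulli(0.5)).  Initial diameters are
    lognormal with a 15 cm median, truncated to [10 cm, species maximum]:
    the inventory design only follows trees above 10 cm DBH.  ``vigor_mode``
    selects how the individual growth error evolves: redrawn each interval
    (``iid``, the inference model's assumption), constant per tree
    (``per_tree``), or autoregressive with coefficient ``ar1_coef``
    (``ar1``) — the latter two are simulator-only scenarios.
    """

    n_trees: int = 17151
    n_censuses: int = 3
    interval_years: float = 10.0
    n_species: int = 335
    trait_ranges: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(TRAIT_RANGES))
    ortho_p: float = 0.5
    params: JointParams = field(default_factory=reference_params)
    init_dbh_median_cm: float = 15.0
    init_dbh_log_sd: float = 0.6
    dbh_floor_cm: float = 10.0
    vigor_mode: str = "iid"
    ar1_coef: float = 0.7
    width_link: str = "linear"
    first_interval_vigor: str = "zero"

    def __post_init__(self):
        if self.n_censuses < 2:
            raise ValueError("n_censuses must be >= 2")
        if self.interval_years <= 0:
            raise ValueError("interval_years must be positive")
        if self.vigor_mode not in VIGOR_MODES:
            raise ValueError(f"vigor_mode must be one of {VIGOR_MODES}")
        if self.first_interval_vigor not in FIRST_INTERVAL_MODES:
            raise ValueError(f"first_interval_vigor must be one of {FIRST_INTERVAL_MODES}")
        for name, (lo, hi) in self.trait_ranges.items():
            if hi < lo:
                raise ValueError(f"empty range for trait {name!r}")
        if min(self.trait_ranges["dbh95_m"]) <= 0 or min(self.trait_ranges["wd"]) <= 0:
            raise ValueError("dbh95_m and wd ranges must be positive")


def sample_species_traits(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw a species trait table, each numeric trait uniform in range."""
    n = config.n_species
    cols = {"species_id": [f"sp{i:04d}" for i in range(n)]}
    for name in ("dbh95_m", "hmax_dm", "wd", "tough", "d13c"):
        lo, hi = config.trait_ranges[name]
        cols[name] = rng.uniform(lo, hi, size=n)
    cols["ortho"] = rng.binomial(1, config.ortho_p, size=n)
    df = pd.DataFrame(cols)[["species_id", "dbh95_m", "hmax_dm", "ortho", "wd", "tough", "d13c"]]
    return df.set_index("species_id")


def _initial_diameters(rng, config: SimConfig, dbh95_m: np.ndarray) -> np.ndarray:
    """Truncated-lognormal starting diameters (cm), per tree."""
    cap = m_to_cm(dbh95_m)
    lo = np.full_like(cap, config.dbh_floor_cm)
    lo = np.minimum(lo, cap * 0.95)  # degenerate species: keep support non-empty
    d = np.empty(dbh95_m.size)
    todo = np.ones(dbh95_m.size, dtype=bool)
    mu = np.log(config.init_dbh_median_cm)
    for _ in range(1000):
        k = int(todo.sum())
        if k == 0:
            break
        draw = np.exp(rng.normal(mu, config.init_dbh_log_sd, size=k))
        d[todo] = draw
        ok = (draw >= lo[todo]) & (draw <= cap[todo])
        idx = np.where(todo)[0]
        todo[idx[ok]] = False
    if todo.any():  # exhaust: clamp the stragglers into range
        d[todo] = np.clip(d[todo], lo[todo], cap[todo])
    return d


@dataclass
class SimResult:
    """Simulated census plus the ground truth that generated it."""

    census: CensusTable
    traits: pd.DataFrame
    truth: Dict
    death_interval: Optional[np.ndarray] = None
    vigor_frames: Optional[list] = None

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_census(self.census, outdir / "census.csv")
        write_traits(self.traits, outdir / "traits.csv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=float)


def simulate_census(config: SimConfig, seed) -> SimResult:
    """Simulate one community forward through the census design.

    Per interval and per alive tree: draw log-growth mu(D) + eps (eps per
    ``vigor_mode``), update the diameter, draw death Bernoulli(p) with p
    from the mortality submodel using the lagged vigor (zero for the
    first interval, as in inference).  A tree dying in interval k gets a
    dead record at census k with no diameter and no further records.
    """
    rng = np.random.default_rng(seed)
    params = config.params
    basis = default_basis()
    traits = sample_species_traits(config, rng)

    species_idx = rng.integers(0, config.n_species, size=config.n_trees)
    sp = traits.reset_index()
    species_id = sp["species_id"].to_numpy()[species_idx]
    dbh95 = sp["dbh95_m"].to_numpy()[species_idx]
    hmax = sp["hmax_dm"].to_numpy()[species_idx]
    ortho = sp["ortho"].to_numpy(dtype=float)[species_idx]
    wd = sp["wd"].to_numpy()[species_idx]
    tough = sp["tough"].to_numpy()[species_idx]
    d13c = sp["d13c"].to_numpy()[species_idx]

    n = config.n_trees
    tree_id = np.array([f"t{i:06d}" for i in range(n)])
    dbh = _initial_diameters(rng, config, dbh95)
    alive = np.ones(n, dtype=bool)
    theta = params.theta_eff()
    beta = params.beta_eff()
    dt = config.interval_years

    eps_per_tree = rng.normal(0.0, params.sigma, size=n)  # per_tree / ar1 state
    lagged_vigor = np.zeros(n)
    has_lag = np.zeros(n, dtype=bool)

    records = {
        "tree_id": [tree_id], "species_id": [species_id],
        "time_index": [np.zeros(n, dtype=int)], "time_years": [np.zeros(n)],
        "dbh_cm": [dbh.copy()], "status": [np.full(n, "alive", dtype=object)],
    }
    death_interval = np.full(n, -1, dtype=int)
    deaths_per_interval = []
    vigor_series = []

    for k in range(1, config.n_censuses):
        idx = np.where(alive)[0]
        mu = expected_log_growth(dbh[idx], dbh95[idx], wd[idx], hmax[idx],
                                 d13c[idx], theta, width_link=config.width_link)
        if config.vigor_mode == "iid":
            eps = rng.normal(0.0, params.sigma, size=idx.size)
        elif config.vigor_mode == "per_tree":
            eps = eps_per_tree[idx]
        else:  # ar1, stationary marginal sd = sigma
            rho = config.ar1_coef
            if k == 1:
                eps = eps_per_tree[idx]
            else:
                innov = rng.normal(0.0, params.sigma * np.sqrt(1 - rho * rho), size=idx.size)
                eps = rho * eps_per_tree[idx] + innov
            eps_per_tree[idx] = eps
        log_growth = mu + eps
        agr = np.expm1(log_growth)                    # mm/yr, may be negative
        new_dbh = dbh[idx] + agr * dt / 10.0          # mm -> cm over dt years

        # mortality over (k-1, k]: lagged vigor, diameter at interval start
        v = np.where(has_lag[idx], lagged_vigor[idx], 0.0)
        x = dbh[idx] / m_to_cm(dbh95[idx])
        eta = linear_predictor_arrays(v, x, hmax[idx], ortho[idx], wd[idx],
                                      tough[idx], beta, basis, params.intercept)
        p = expit(eta)
        dies = rng.random(idx.size) < p
        deaths_per_interval.append(int(dies.sum()))
        vigor_series.append(pd.DataFrame({
            "tree_id": tree_id[idx], "interval_index": k,
            "vigor": v, "eps": eps, "p_death": p, "died": dies,
        }))

        # records at census k
        surv = idx[~dies]
        dead = idx[dies]
        death_interval[dead] = k
        alive[dead] = False
        dbh[surv] = new_dbh[~dies]
        # lagged vigor for interval k+1 = this interval's growth residual,
        # computed exactly as inference will see it (clamped at zero growth)
        obs_y = np.log1p(np.maximum(agr[~dies], 0.0))
        lagged_vigor[surv] = obs_y - mu[~dies]
        has_lag[surv] = True

        n_rec = idx.size
        records["tree_id"].append(tree_id[idx])
        records["species_id"].append(species_id[idx])
        records["time_index"].append(np.full(n_rec, k, dtype=int))
        records["time_years"].append(np.full(n_rec, k * dt))
        rec_dbh = np.where(dies, np.nan, new_dbh)
        records["dbh_cm"].append(rec_dbh)
        records["status"].append(np.where(dies, "dead", "alive").astype(object))

    frame = pd.DataFrame({key: np.concatenate(vals) for key, vals in records.items()})
    census = census_from_frame(frame, config.interval_years)

    truth = {
        "params": {k: v for k, v in params.as_series().items()},
        "seed": int(seed) if np.isscalar(seed) else None,
        "n_trees": n,
        "n_censuses": config.n_censuses,
        "interval_years": dt,
        "n_species": config.n_species,
        "vigor_mode": config.vigor_mode,
        "deaths_per_interval": deaths_per_interval,
        "n_deaths": int((death_interval > 0).sum()),
    }
    return SimResult(census=census, traits=traits, truth=truth,
                     death_interval=death_interval, vigor_frames=vigor_series)
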
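"""Joint likelihood over complete tree trajectories.

Each tree contributes a product of interval factors.  A survivor observed
at censuses 0..T contributes, for every interval t in 1..T, the growth
transition density f(D_t | D_{t-1}) and the survival probability
(1 - p_t).  A tree dying in interval (k-1, k] contributes the growth and
survival factors up to k-1 and the death probability p_k; there is no
growth factor for the death interval because the tree has no final
diameter.  The death probability of interval t uses the lagged vigor, the
growth residual of interval t-1; a tree's first interval has no lagged
growth and its vigor defaults to zero (the residual's prior mean), or the
interval can be dropped from the mortality factor entirely.

All computation is in log space.  Two code paths exist: a per-tree
reference path (:func:`tree_loglik`, readable, used on
:class:`TreeTrajectory` objects) and a vectorized path over a prebuilt
:class:`JointData` design (used by the sampler).
"""

from __future__ import annotations

import logging
import math
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    STATUS_ALIVE,
    STATUS_DEAD,
    CensusTable,
    JointParams,
    TraitVector,
    trait_vector,
)
from .growth import GrowthParams, expected_log_growth, gaussian_loglik, predict_log_growth
from .mortality import (
    MortalityParams,
    OntogenyBasis,
    bernoulli_loglik,
    compute_vigor,
    default_basis,
    mortality_linear_predictor,
)
from .units import m_to_cm

logger = logging.getLogger("treevigor")

LoglikComponents = namedtuple("LoglikComponents", ["total", "growth", "mortality"])

FIRST_INTERVAL_MODES = ("zero", "drop")


@dataclass
class TreeTrajectory:
    """One tree's complete observed history.

    ``dbhs`` holds the diameter (cm) at each census while alive, None
    otherwise.  ``death_interval`` is the interval index k if the tree
    died in (k-1, k], else None.
    """

    tree_id: object
    traits: TraitVector
    time_indices: List[int]
    dbhs: List[Optional[float]]
    statuses: List[str]
    death_interval: Optional[int] = None


def build_trajectories(census: CensusTable, traits: pd.DataFrame) -> List[TreeTrajectory]:
    """Assemble per-tree trajectories from a census and a trait table."""
    out = []
    for tid, grp in census.usable_frame().groupby("tree_id", sort=False):
        tv = trait_vector(traits, grp["species_id"].iloc[0])
        statuses = grp["status"].tolist()
        times = grp["time_index"].tolist()
        dbhs = [float(d) if np.isfinite(d) else None for d in grp["dbh_cm"].to_numpy(dtype=float)]
        death = None
        for t, s in zip(times, statuses):
            if s == STATUS_DEAD:
                death = t
                break
        out.append(TreeTrajectory(tree_id=tid, traits=tv, time_indices=times,
                                  dbhs=dbhs, statuses=statuses, death_interval=death))
    return out


def _observed_log_agr1(d_prev: float, d_next: float, interval_years: float) -> float:
    agr = 10.0 * (d_next - d_prev) / interval_years
    return math.log1p(max(agr, 0.0))


def tree_loglik_components(traj: TreeTrajectory, params: JointParams, *,
                           interval_years: float,
                           basis: Optional[OntogenyBasis] = None,
                           width_link: str = "linear",
                           first_interval_vigor: str = "zero") -> LoglikComponents:
    """Reference (non-vectorized) per-tree log-likelihood, by component."""
    basis = basis or default_basis()
    gp = GrowthParams.from_joint(params, width_link=width_link)
    mp = MortalityParams.from_joint(params, basis=basis)
    tv = traj.traits

    ll_g = 0.0
    ll_m = 0.0
    records = list(zip(traj.time_indices, traj.dbhs, traj.statuses))
    for j in range(1, len(records)):
        t_prev, d_prev, s_prev = records[j - 1]
        t_cur, d_cur, s_cur = records[j]
        if t_cur - t_prev != 1 or s_prev != STATUS_ALIVE:
            continue
        # growth factor: both endpoints alive with measured diameters
        if s_cur == STATUS_ALIVE and d_prev is not None and d_cur is not None:
            y = _observed_log_agr1(d_prev, d_cur, interval_years)
            mu = predict_log_growth(d_prev, tv, gp)
            ll_g += gaussian_loglik(np.array([y]), np.array([mu]), gp.sigma)
        # mortality factor: outcome observed at t_cur
        if s_cur in (STATUS_ALIVE, STATUS_DEAD) and d_prev is not None:
            vigor = None
            if j >= 2:
                t_pp, d_pp, s_pp = records[j - 2]
                if (t_prev - t_pp == 1 and s_pp == STATUS_ALIVE
                        and d_pp is not None and d_prev is not None):
                    y_prev = _observed_log_agr1(d_pp, d_prev, interval_years)
                    vigor = compute_vigor(y_prev, predict_log_growth(d_pp, tv, gp))
            if vigor is None:
                if first_interval_vigor == "drop":
                    continue
                vigor = 0.0
            eta = mortality_linear_predictor(float(vigor), d_prev, tv, mp)
            ll_m += bernoulli_loglik(np.array([eta]), np.array([s_cur == STATUS_DEAD]))
    total = ll_g + ll_m
    if not np.isfinite(total):
        total = -np.inf
    return LoglikComponents(total, ll_g, ll_m)


def tree_loglik(traj: TreeTrajectory, params: JointParams, **kwargs) -> float:
    """Joint log-likelihood contribution of one tree (see module docstring)."""
    return tree_loglik_components(traj, params, **kwargs).total


@dataclass
class JointData:
    """Vectorized design of the joint likelihood for one census data set.

    Growth block (one row per alive->alive interval with diameters):
    observed log(AGR+1), starting diameter and the four growth traits.
    Mortality block (one row per interval with an observed alive/dead
    outcome): static covariate columns (ontogeny-basis values and the
    four mortality traits), the death indicator, and ``m_vidx`` pointing
    at the growth row of the preceding interval that supplies the lagged
    vigor (-1 when none; vigor 0 under the default first-interval rule).
    """

    # growth block
    g_y: np.ndarray
    g_dbh: np.ndarray
    g_dbh95: np.ndarray
    g_wd: np.ndarray
    g_hmax: np.ndarray
    g_d13c: np.ndarray
    # mortality block
    m_vidx: np.ndarray
    m_x: np.ndarray
    m_died: np.ndarray
    m_cols: Dict[str, np.ndarray]
    # bookkeeping
    basis: OntogenyBasis
    width_link: str
    first_interval_vigor: str
    interval_years: float
    n_trees: int
    n_clamped: int
    g_frame: pd.DataFrame = field(repr=False, default=None)
    m_frame: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_growth(self) -> int:
        return self.g_y.size

    @property
    def n_mortality(self) -> int:
        return self.m_died.size

    @classmethod
    def from_census(cls, census: CensusTable, traits: pd.DataFrame, *,
                    basis: Optional[OntogenyBasis] = None,
                    width_link: str = "linear",
                    first_interval_vigor: str = "zero",
                    individual_traits: Optional[pd.DataFrame] = None) -> "JointData":
        """Build the design from a validated census and trait table.

        ``individual_traits`` optionally overrides the species-level trait
        values per tree (columns = trait columns, indexed by tree_id): a
        hook for propagating per-individual trait uncertainty by
        resampling the design between sampler sweeps.
        """
        if first_interval_vigor not in FIRST_INTERVAL_MODES:
            raise ValueError(f"first_interval_vigor must be one of {FIRST_INTERVAL_MODES}")
        basis = basis or default_basis()

        df = census.usable_frame().reset_index(drop=True)
        trait_cols = ["dbh95_m", "hmax_dm", "ortho", "wd", "tough", "d13c"]
        df = df.join(traits[trait_cols], on="species_id")
        if df["dbh95_m"].isna().any():
            missing = df.loc[df["dbh95_m"].isna(), "species_id"].unique()[:5]
            raise ValueError(f"species missing from trait table: {list(missing)}")
        if individual_traits is not None:
            over = individual_traits.reindex(df["tree_id"])
            for col in trait_cols:
                if col in over.columns:
                    vals = over[col].to_numpy(dtype=float)
                    df[col] = np.where(np.isfinite(vals), vals, df[col])

        same_tree = df["tree_id"].eq(df["tree_id"].shift())
        consec = same_tree & df["time_index"].diff().eq(1)
        prev_alive = df["status"].shift().eq(STATUS_ALIVE)
        cur_alive = df["status"] == STATUS_ALIVE
        cur_dead = df["status"] == STATUS_DEAD

        prev = df.shift()

        # --- growth block ---
        g_mask = consec & prev_alive & cur_alive & prev["dbh_cm"].notna() & df["dbh_cm"].notna()
        gs, gp = df.loc[g_mask], prev.loc[g_mask]
        raw_agr = 10.0 * (gs["dbh_cm"].to_numpy() - gp["dbh_cm"].to_numpy()) / census.interval_years
        clamped = raw_agr < 0
        g_y = np.log1p(np.where(clamped, 0.0, raw_agr))
        g_frame = pd.DataFrame({
            "tree_id": gs["tree_id"].to_numpy(),
            "interval_index": gs["time_index"].to_numpy(),
        })

        # --- mortality block ---
        m_mask = consec & prev_alive & (cur_alive | cur_dead) & prev["dbh_cm"].notna()
        ms = df.loc[m_mask]
        mp_ = prev.loc[m_mask]
        m_died = cur_dead[m_mask].to_numpy()
        m_frame = pd.DataFrame({
            "tree_id": ms["tree_id"].to_numpy(),
            "interval_index": ms["time_index"].to_numpy(),
        })
        # lagged-vigor source: growth row of (tree, interval-1)
        g_key = pd.MultiIndex.from_arrays(
            [g_frame["tree_id"], g_frame["interval_index"]])
        g_lookup = pd.Series(np.arange(len(g_frame)), index=g_key)
        m_key = pd.MultiIndex.from_arrays(
            [m_frame["tree_id"], m_frame["interval_index"] - 1])
        m_vidx = g_lookup.reindex(m_key).fillna(-1).to_numpy(dtype=np.int64)

        if first_interval_vigor == "drop":
            keep = m_vidx >= 0
            ms = ms.loc[keep]
            mp_ = mp_.loc[keep]
            m_died = m_died[keep]
            m_frame = m_frame.loc[keep].reset_index(drop=True)
            m_vidx = m_vidx[keep]

        x = mp_["dbh_cm"].to_numpy() / m_to_cm(mp_["dbh95_m"].to_numpy())
        m_cols = {
            "beta1": np.asarray(basis.f1(x), dtype=float),
            "beta2": np.asarray(basis.f2(x), dtype=float),
            "beta3": mp_["hmax_dm"].to_numpy(dtype=float),
            "beta4": mp_["ortho"].to_numpy(dtype=float),
            "beta5": mp_["wd"].to_numpy(dtype=float),
            "beta6": mp_["tough"].to_numpy(dtype=float),
        }

        n_clamped = int(clamped.sum())
        if n_clamped:
            logger.info("joint design: %d clamped growth observations", n_clamped)

        return cls(
            g_y=g_y,
            g_dbh=gp["dbh_cm"].to_numpy(dtype=float),
            g_dbh95=gp["dbh95_m"].to_numpy(dtype=float),
            g_wd=gp["wd"].to_numpy(dtype=float),
            g_hmax=gp["hmax_dm"].to_numpy(dtype=float),
            g_d13c=gp["d13c"].to_numpy(dtype=float),
            m_vidx=m_vidx,
            m_x=x,
            m_died=m_died.astype(bool),
            m_cols=m_cols,
            basis=basis,
            width_link=width_link,
            first_interval_vigor=first_interval_vigor,
            interval_years=census.interval_years,
            n_trees=census.n_usable_trees,
            n_clamped=n_clamped,
            g_frame=g_frame,
            m_frame=m_frame,
        )

    # --- vectorized likelihood pieces (used by the sampler's caches) ---

    def growth_mu(self, theta_eff: Sequence[float]) -> np.ndarray:
        return expected_log_growth(self.g_dbh, self.g_dbh95, self.g_wd,
                                   self.g_hmax, self.g_d13c, theta_eff,
                                   width_link=self.width_link)

    def vigor_from_resid(self, resid: np.ndarray) -> np.ndarray:
        if resid.size == 0:
            return np.zeros(self.n_mortality)
        v = resid.take(np.where(self.m_vidx >= 0, self.m_vidx, 0))
        return np.where(self.m_vidx >= 0, v, 0.0)

    def eta_static(self, beta_eff: Sequence[float], intercept=None) -> np.ndarray:
        eta = np.zeros(self.n_mortality)
        for j, name in enumerate(("beta1", "beta2", "beta3", "beta4", "beta5", "beta6"), start=1):
            b = float(beta_eff[j])
            if b != 0.0:
                eta = eta + b * self.m_cols[name]
        if intercept is not None:
            eta = eta + float(intercept)
        return eta

    def mortality_loglik(self, eta: np.ndarray) -> float:
        return bernoulli_loglik(eta, self.m_died)

    def loglik(self, params: JointParams) -> LoglikComponents:
        """Full joint log-likelihood, growth and mortality components."""
        mu = self.growth_mu(params.theta_eff())
        resid = self.g_y - mu
        ll_g = gaussian_loglik(self.g_y, mu, params.sigma)
        beta_eff = params.beta_eff()
        eta = self.eta_static(beta_eff, params.intercept) + beta_eff[0] * self.vigor_from_resid(resid)
        ll_m = self.mortality_loglik(eta)
        total = ll_g + ll_m
        if not np.isfinite(total):
            total = -np.inf
        return LoglikComponents(total, ll_g, ll_m)


def total_loglik(data: Union[JointData, Iterable[TreeTrajectory]],
                 params: JointParams, **kwargs) -> LoglikComponents:
    """Joint log-likelihood of a data set, with components.

    Accepts either a prebuilt :class:`JointData` design (fast, vectorized)
    or an iterable of :class:`TreeTrajectory` (reference path; extra
    keyword arguments are forwarded to :func:`tree_loglik_components`).
    Returns (total, growth, mortality); any non-finite contribution makes
    the total -inf and is logged with the offending tree when known.
    """
    if isinstance(data, JointData):
        return data.loglik(params)
    ll_g = ll_m = 0.0
    for traj in data:
        c = tree_loglik_components(traj, params, **kwargs)
        if not np.isfinite(c.total):
            logger.info("non-finite likelihood for tree %r", traj.tree_id)
            return LoglikComponents(-np.inf, ll_g + c.growth, ll_m + c.mortality)
        ll_g += c.growth
        ll_m += c.mortality
    return LoglikComponents(ll_g + ll_m, ll_g, ll_m)
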
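"""Domain types and census/trait table I-O.

The package works on two delimited-text inputs:

* a tree census table, one record per tree per census:
  ``tree_id,species_id,time_index,time_years,dbh_cm,status`` with
  ``status`` in ``{alive, dead, unobserved}`` and ``dbh_cm`` present iff
  the tree is alive;
* a species trait table with the six community functional traits:
  ``species_id,dbh95_m,hmax_dm,ortho,wd,tough,d13c``.

Validation is strict: a dead record carrying a diameter, duplicate
(tree, census) pairs, or records after death are parse errors naming the
offending tree.  Trees that cannot enter the likelihood (a single record,
irregular census spacing) are flagged unusable with a reason rather than
silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .units import annualized_increment_mm

logger = logging.getLogger("treevigor")

STATUS_ALIVE = "alive"
STATUS_DEAD = "dead"
STATUS_UNOBSERVED = "unobserved"
VALID_STATUS = (STATUS_ALIVE, STATUS_DEAD, STATUS_UNOBSERVED)

CENSUS_COLUMNS = ("tree_id", "species_id", "time_index", "time_years", "dbh_cm", "status")
TRAIT_COLUMNS = ("species_id", "dbh95_m", "hmax_dm", "ortho", "wd", "tough", "d13c")

#: Plausible community ranges of the six functional traits (used as the
#: synthetic generator's sampling defaults; the readers do not enforce them).
#: dbh95 in m, hmax in dm, wd in g cm^-3, tough in N, d13c in permil.
TRAIT_RANGES: Dict[str, Tuple[float, float]] = {
    "dbh95_m": (0.13, 1.11),
    "hmax_dm": (0.8, 5.6),
    "wd": (0.28, 0.91),
    "tough": (0.22, 11.4),
    "d13c": (-3.61, -2.62),
}

#: The eight predictors eligible for Bayesian indicator selection: four
#: traits of the growth process and four of the mortality process.
CANDIDATE_PREDICTORS = (
    "theta1",  # growth: DBH95
    "theta2",  # growth: WD
    "theta3",  # growth: Hmax
    "theta4",  # growth: d13C
    "beta3",   # mortality: Hmax
    "beta4",   # mortality: Ortho
    "beta5",   # mortality: WD
    "beta6",   # mortality: Tough
)

THETA_NAMES = ("theta1", "theta2", "theta3", "theta4", "theta5", "theta6")
BETA_NAMES = ("beta0", "beta1", "beta2", "beta3", "beta4", "beta5", "beta6")
PARAM_NAMES = THETA_NAMES + ("sigma",) + BETA_NAMES


class CensusParseError(ValueError):
    """A census file violates a structural invariant."""


class ParameterError(ValueError):
    """A parameter vector is outside its mathematical domain."""


@dataclass(frozen=True)
class TraitVector:
    """The six species-level functional traits used as covariates.

    Attributes
    ----------
    dbh95 : float
        Species maximum diameter (DBH95/DBHmax), in metres.
    hmax : float
        Species maximum height, in the community table's dm convention.
    ortho : int
        Stem/branch orientation: 1 orthotropic, 0 plagiotropic.
    wd : float
        Trunk xylem (wood) density, g cm^-3.
    tough : float
        Laminar toughness, N.
    d13c : float
        Foliar delta-13C composition, permil.
    """

    dbh95: float
    hmax: float
    ortho: int
    wd: float
    tough: float
    d13c: float

    def __post_init__(self):
        if not np.isfinite([self.dbh95, self.hmax, self.wd, self.tough, self.d13c]).all():
            raise ParameterError("trait values must be finite")
        if self.dbh95 <= 0:
            raise ParameterError("dbh95 must be positive")
        if self.wd <= 0:
            raise ParameterError("wd must be positive")
        if self.ortho not in (0, 1):
            raise ParameterError("ortho must be 0 or 1")


@dataclass
class JointParams:
    """Joint parameter vector of the coupled growth-mortality model.

    theta1..theta4 weight the four growth traits in the maximum log-growth,
    theta5 is the relative diameter at maximum growth (fraction of DBH95),
    theta6 the growth-curve width coefficient (paired with wood density),
    and sigma the residual s.d. of log(AGR+1) (the seventh growth
    parameter).  beta0 multiplies the vigor covariate; beta1/beta2 the two
    ontogenetic-trajectory covariates; beta3..beta6 the four mortality
    traits.  ``gamma`` carries the binary inclusion indicator of each
    selectable predictor; a deselected predictor contributes exactly zero
    to every linear predictor while its coefficient keeps its value.
    """

    theta1: float = 0.0
    theta2: float = 0.0
    theta3: float = 0.0
    theta4: float = 0.0
    theta5: float = 1.0
    theta6: float = 1.0
    sigma: float = 1.0
    beta0: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    beta4: float = 0.0
    beta5: float = 0.0
    beta6: float = 0.0
    intercept: Optional[float] = None
    gamma: Dict[str, int] = field(
        default_factory=lambda: {name: 1 for name in CANDIDATE_PREDICTORS}
    )

    def __post_init__(self):
        if self.sigma <= 0:
            raise ParameterError("sigma (theta7) must be positive")
        if self.theta5 <= 0:
            raise ParameterError("theta5 must be positive")
        for name, g in self.gamma.items():
            if name not in CANDIDATE_PREDICTORS:
                raise ParameterError(f"unknown selectable predictor {name!r}")
            if g not in (0, 1):
                raise ParameterError("gamma entries must be 0 or 1")

    def effective(self, name: str) -> float:
        """Coefficient value after applying its inclusion indicator."""
        return getattr(self, name) * self.gamma.get(name, 1)

    def theta_eff(self) -> np.ndarray:
        """Effective theta1..theta6 as an array (gamma-masked)."""
        return np.array([self.effective(n) for n in THETA_NAMES])

    def beta_eff(self) -> np.ndarray:
        """Effective beta0..beta6 as an array (gamma-masked)."""
        return np.array([self.effective(n) for n in BETA_NAMES])

    def replace(self, **kwargs) -> "JointParams":
        if "gamma" not in kwargs:
            kwargs["gamma"] = dict(self.gamma)
        return replace(self, **kwargs)

    def as_series(self) -> pd.Series:
        vals = {n: getattr(self, n) for n in PARAM_NAMES}
        for name in CANDIDATE_PREDICTORS:
            vals[f"gamma_{name}"] = self.gamma.get(name, 1)
        if self.intercept is not None:
            vals["intercept"] = self.intercept
        return pd.Series(vals)

    @classmethod
    def from_mapping(cls, values: Mapping[str, float]) -> "JointParams":
        gamma = {n: 1 for n in CANDIDATE_PREDICTORS}
        kwargs = {}
        for key, val in values.items():
            if key.startswith("gamma_"):
                gamma[key[len("gamma_"):]] = int(round(val))
            elif key in PARAM_NAMES or key == "intercept":
                kwargs[key] = float(val)
        return cls(gamma=gamma, **kwargs)


@dataclass
class CensusTable:
    """A validated longitudinal census: diameters and vital status.

    ``frame`` is sorted by (tree_id, time_index).  ``unusable`` maps tree
    ids excluded from likelihood construction to a human-readable reason.
    """

    frame: pd.DataFrame
    interval_years: float
    unusable: Dict[object, str] = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return self.frame["tree_id"].nunique()

    @property
    def n_usable_trees(self) -> int:
        return self.n_trees - len(self.unusable)

    def usable_frame(self) -> pd.DataFrame:
        if not self.unusable:
            return self.frame
        return self.frame[~self.frame["tree_id"].isin(self.unusable)]

    def write(self, path) -> None:
        write_census(self, path)


def _validate_census_frame(df: pd.DataFrame, interval_years: float) -> Tuple[pd.DataFrame, Dict[object, str]]:
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise CensusParseError(f"census table is missing columns: {missing}")
    df = df.loc[:, list(CENSUS_COLUMNS)].copy()
    bad_status = ~df["status"].isin(VALID_STATUS)
    if bad_status.any():
        tid = df.loc[bad_status, "tree_id"].iloc[0]
        raise CensusParseError(f"invalid status for tree {tid!r}")
    df["time_index"] = df["time_index"].astype(int)
    df["time_years"] = df["time_years"].astype(float)
    df["dbh_cm"] = pd.to_numeric(df["dbh_cm"], errors="coerce")

    has_dbh = df["dbh_cm"].notna()
    alive = df["status"] == STATUS_ALIVE
    offenders = df.loc[has_dbh & ~alive, "tree_id"]
    if len(offenders):
        raise CensusParseError(
            f"dbh present on non-alive record for tree {offenders.iloc[0]!r}"
        )
    offenders = df.loc[alive & ~has_dbh, "tree_id"]
    if len(offenders):
        raise CensusParseError(
            f"alive record without dbh for tree {offenders.iloc[0]!r}"
        )
    if (df.loc[has_dbh, "dbh_cm"] <= 0).any():
        tid = df.loc[has_dbh & (df["dbh_cm"] <= 0), "tree_id"].iloc[0]
        raise CensusParseError(f"non-positive dbh for tree {tid!r}")

    df = df.sort_values(["tree_id", "time_index"], kind="mergesort").reset_index(drop=True)
    if df.duplicated(["tree_id", "time_index"]).any():
        tid = df.loc[df.duplicated(["tree_id", "time_index"]), "tree_id"].iloc[0]
        raise CensusParseError(f"duplicate (tree, census) record for tree {tid!r}")

    unusable: Dict[object, str] = {}
    grp = df.groupby("tree_id", sort=False)
    sizes = grp.size()
    for tid in sizes.index[sizes < 2]:
        unusable[tid] = "fewer than 2 census records"

    # Records after a death, and spacing checks, per tree.
    same_tree = df["tree_id"].eq(df["tree_id"].shift())
    prev_dead = df["status"].shift().eq(STATUS_DEAD) & same_tree
    if prev_dead.any():
        tid = df.loc[prev_dead, "tree_id"].iloc[0]
        raise CensusParseError(f"record after death for tree {tid!r}")

    dt_index = df["time_index"].diff()
    dt_years = df["time_years"].diff()
    irregular = same_tree & (
        (dt_index != 1) | (np.abs(dt_years - dt_index * interval_years) > 1e-6)
    )
    for tid in df.loc[irregular, "tree_id"].unique():
        unusable.setdefault(tid, "irregular census spacing")

    if unusable:
        logger.info("census: %d of %d trees flagged unusable",
                    len(unusable), df["tree_id"].nunique())
    return df, unusable


def census_from_frame(df: pd.DataFrame, interval_years: float) -> CensusTable:
    """Validate a raw dataframe into a :class:`CensusTable`."""
    frame, unusable = _validate_census_frame(df, interval_years)
    return CensusTable(frame=frame, interval_years=float(interval_years), unusable=unusable)


def read_census(path, interval_years: float) -> CensusTable:
    """Read and validate a comma-delimited census file."""
    df = pd.read_csv(path)
    return census_from_frame(df, interval_years)


def write_census(census: CensusTable, path) -> None:
    out = census.frame.copy()
    out.to_csv(path, index=False)


def read_traits(path) -> pd.DataFrame:
    """Read a species trait table, indexed by species_id."""
    df = pd.read_csv(path)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise CensusParseError(f"trait table is missing columns: {missing}")
    df = df.loc[:, list(TRAIT_COLUMNS)]
    if df["species_id"].duplicated().any():
        raise CensusParseError("duplicate species_id in trait table")
    numeric = df[["dbh95_m", "hmax_dm", "wd", "tough", "d13c"]].to_numpy(dtype=float)
    if not np.isfinite(numeric).all():
        raise CensusParseError("non-finite trait value")
    if (df["dbh95_m"] <= 0).any() or (df["wd"] <= 0).any():
        raise CensusParseError("dbh95_m and wd must be positive")
    if not df["ortho"].isin([0, 1]).all():
        raise CensusParseError("ortho must be 0 or 1")
    return df.set_index("species_id")


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.reset_index().to_csv(path, index=False)


def trait_vector(traits: pd.DataFrame, species_id) -> TraitVector:
    row = traits.loc[species_id]
    return TraitVector(
        dbh95=float(row["dbh95_m"]),
        hmax=float(row["hmax_dm"]),
        ortho=int(row["ortho"]),
        wd=float(row["wd"]),
        tough=float(row["tough"]),
        d13c=float(row["d13c"]),
    )


def compute_growth_observations(census: CensusTable) -> pd.DataFrame:
    """Annualized growth observations from alive->alive consecutive pairs.

    Returns one row per census interval whose two endpoints are both alive
    with measured diameters: ``tree_id, species_id, interval_index,
    dbh_prev_cm, dbh_cm, agr_mm_yr, log_agr1, clamped``.  ``interval_index``
    is the index k of the interval (k-1, k].  Negative raw increments are
    clamped to zero before the log transform (log(AGR+1) requires AGR > -1;
    field shrinkage is treated as measurement noise); the number of clamped
    observations is logged and stored in ``result.attrs['n_clamped']``.
    """
    df = census.usable_frame()
    same_tree = df["tree_id"].eq(df["tree_id"].shift())
    prev_alive = df["status"].shift().eq(STATUS_ALIVE)
    cur_alive = df["status"].eq(STATUS_ALIVE)
    eligible = same_tree & prev_alive & cur_alive
    sub = df.loc[eligible]
    prev = df.shift().loc[eligible]

    raw_agr = annualized_increment_mm(
        prev["dbh_cm"].to_numpy(), sub["dbh_cm"].to_numpy(), census.interval_years
    )
    clamped = raw_agr < 0
    agr = np.where(clamped, 0.0, raw_agr)
    out = pd.DataFrame(
        {
            "tree_id": sub["tree_id"].to_numpy(),
            "species_id": sub["species_id"].to_numpy(),
            "interval_index": sub["time_index"].to_numpy(),
            "dbh_prev_cm": prev["dbh_cm"].to_numpy(),
            "dbh_cm": sub["dbh_cm"].to_numpy(),
            "agr_mm_yr": agr,
            "log_agr1": np.log1p(agr),
            "clamped": clamped,
        }
    ).reset_index(drop=True)
    n_clamped = int(clamped.sum())
    out.attrs["n_clamped"] = n_clamped
    if n_clamped:
        logger.info("growth observations: %d of %d negative increments clamped to 0",
                    n_clamped, len(out))
    return out
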
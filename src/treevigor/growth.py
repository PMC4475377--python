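"""Hump-shaped, trait-driven individual growth submodel.

The modeled quantity is log(AGR+1) with AGR the annualized diameter
increment in mm/yr.  A tree of diameter D (cm) belonging to a species with
traits (DBH95, WD, Hmax, d13C) grows on average

    mu(D) = Gmax * exp( -1/2 * [ log(D / Dopt) / K ]^2 )

where the species maximum log-growth is a linear combination of four
traits,

    Gmax = theta1*DBH95 + theta2*WD + theta3*Hmax + theta4*d13C,

the diameter at maximum growth is a fixed fraction of the species maximum
diameter, Dopt = theta5 * DBH95 (compared with D in a common unit), and
the curve width is driven by wood density, K = theta6 * WD by default
(denser-wooded species modulate growth less).  Observed log-growth is
Gaussian around mu with standard deviation sigma, drawn independently per
tree and interval; this residual is the tree's vigor (see
:mod:`treevigor.mortality`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import JointParams, ParameterError, TraitVector
from .units import m_to_cm

_LOG_2PI = float(np.log(2.0 * np.pi))

WIDTH_LINKS = ("linear", "power")


@dataclass(frozen=True)
class GrowthParams:
    """Growth submodel parameters (theta1..theta6 plus the residual sd)."""

    theta1: float
    theta2: float
    theta3: float
    theta4: float
    theta5: float
    theta6: float
    sigma: float
    width_link: str = "linear"

    def __post_init__(self):
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")
        if self.theta5 <= 0:
            raise ParameterError("theta5 (relative diameter at maximum growth) must be positive")
        if self.width_link not in WIDTH_LINKS:
            raise ParameterError(f"width_link must be one of {WIDTH_LINKS}")

    @classmethod
    def from_joint(cls, params: JointParams, width_link: str = "linear") -> "GrowthParams":
        return cls(
            *(params.effective(n) for n in
              ("theta1", "theta2", "theta3", "theta4", "theta5", "theta6")),
            sigma=params.sigma,
            width_link=width_link,
        )

    def theta(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3,
                         self.theta4, self.theta5, self.theta6])


def growth_width(theta6, wd, width_link: str = "linear"):
    """Width K of the log-growth curve for wood density ``wd``."""
    if width_link == "linear":
        return theta6 * np.asarray(wd, dtype=float)
    if width_link == "power":
        return np.asarray(theta6, dtype=float) ** np.asarray(wd, dtype=float)
    raise ParameterError(f"width_link must be one of {WIDTH_LINKS}")


def gmax_from_traits(dbh95_m, wd, hmax_dm, d13c, theta) -> np.ndarray:
    """Species maximum log-growth, linear in the four growth traits."""
    t1, t2, t3, t4 = (float(theta[i]) for i in range(4))
    return (t1 * np.asarray(dbh95_m, dtype=float)
            + t2 * np.asarray(wd, dtype=float)
            + t3 * np.asarray(hmax_dm, dtype=float)
            + t4 * np.asarray(d13c, dtype=float))


def expected_log_growth(dbh_cm, dbh95_m, wd, hmax_dm, d13c, theta,
                        width_link: str = "linear") -> np.ndarray:
    """Expected log(AGR+1) at diameter ``dbh_cm`` (vectorized core).

    ``theta`` is the effective (inclusion-masked) theta1..theta6 sequence.
    Raises :class:`ParameterError` on a non-positive optimum diameter or
    curve width.
    """
    dbh = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh <= 0):
        raise ParameterError("dbh must be positive")
    t5, t6 = float(theta[4]), float(theta[5])
    dopt_cm = t5 * m_to_cm(dbh95_m)
    if t5 <= 0 or np.any(dopt_cm <= 0):
        raise ParameterError("optimum diameter theta5*DBH95 must be positive")
    width = growth_width(t6, wd, width_link)
    if np.any(width <= 0):
        raise ParameterError("growth-curve width must be positive")
    gm = gmax_from_traits(dbh95_m, wd, hmax_dm, d13c, theta)
    z = np.log(dbh / dopt_cm) / width
    return gm * np.exp(-0.5 * z * z)


def gmax(traits: TraitVector, params: GrowthParams) -> float:
    """Maximum log-growth Gmax of a species (attained at D = theta5*DBH95)."""
    return float(gmax_from_traits(traits.dbh95, traits.wd, traits.hmax,
                                  traits.d13c, params.theta()))


def predict_log_growth(dbh_cm: float, traits: TraitVector, params: GrowthParams) -> float:
    """Expected log(AGR+1) for one tree at diameter ``dbh_cm`` (cm)."""
    return float(expected_log_growth(dbh_cm, traits.dbh95, traits.wd, traits.hmax,
                                     traits.d13c, params.theta(),
                                     width_link=params.width_link))


def gaussian_loglik(y, mu, sigma):
    """Sum of Gaussian log-densities of ``y`` around ``mu`` with sd ``sigma``."""
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    y = np.asarray(y, dtype=float)
    r = y - np.asarray(mu, dtype=float)
    n = r.size
    return float(-0.5 * n * (_LOG_2PI + 2.0 * np.log(sigma))
                 - 0.5 * np.dot(r.ravel(), r.ravel()) / (sigma * sigma))


def growth_logdensity(log_agr1: float, dbh_prev_cm: float, traits: TraitVector,
                      params: GrowthParams) -> float:
    """Log transition density log f(D_t | D_{t-1}) for one interval.

    Gaussian log-density of the observed log(AGR+1) around the model
    expectation at the interval's starting diameter.  The Jacobian of the
    diameter -> log(AGR+1) change of variable is parameter-free and
    omitted: it shifts every likelihood by the same constant and cancels
    from every posterior ratio.
    """
    mu = predict_log_growth(dbh_prev_cm, traits, params)
    return gaussian_loglik(np.array([log_agr1]), np.array([mu]), params.sigma)
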
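"""Vigor estimator and vigor-dependent logistic mortality submodel.

Vigor is the residual of the growth model on the modeled log(AGR+1)
scale: v = observed - expected.  A tree growing less than its
species/ontogeny-expected rate has negative vigor.  Mortality over a
census interval is Bernoulli with

    logit p = beta0*v + beta1*f1(x) + beta2*f2(x)
              + beta3*Hmax + beta4*Ortho + beta5*WD + beta6*Tough

where x = D / DBH95 is the ontogenetic stage (diameters in a common
unit) and (f1, f2) is an injectable two-function basis describing the
ontogenetic mortality trajectory.  The default basis f1(x) = x,
f2(x) = 1/x yields the classic U shape: small trees die of suppression,
trees near their maximum size die of senescence.  No separate intercept
is used by default; baseline mortality is absorbed by the ontogeny terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import expit

from .core import JointParams, ParameterError, TraitVector
from .units import m_to_cm


@dataclass(frozen=True)
class OntogenyBasis:
    """Pair of basis functions of the ontogenetic stage x = D/DBH95."""

    f1: Callable[[np.ndarray], np.ndarray]
    f2: Callable[[np.ndarray], np.ndarray]
    name: str = "custom"


def default_basis() -> OntogenyBasis:
    """U-shape basis: f1(x) = x (senescence), f2(x) = 1/x (suppression)."""
    return OntogenyBasis(f1=lambda x: x, f2=lambda x: 1.0 / x, name="x,1/x")


@dataclass(frozen=True)
class MortalityParams:
    """Mortality submodel parameters beta0..beta6 (+ optional intercept)."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    beta4: float
    beta5: float
    beta6: float
    intercept: Optional[float] = None
    basis: OntogenyBasis = field(default_factory=default_basis)

    @classmethod
    def from_joint(cls, params: JointParams,
                   basis: Optional[OntogenyBasis] = None) -> "MortalityParams":
        return cls(
            *(params.effective(n) for n in
              ("beta0", "beta1", "beta2", "beta3", "beta4", "beta5", "beta6")),
            intercept=params.intercept,
            basis=basis or default_basis(),
        )

    def beta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3,
                         self.beta4, self.beta5, self.beta6])


def compute_vigor(observed_log_agr1, predicted_log_agr1):
    """Vigor v = observed - predicted log growth (modeled scale).

    Negative when the tree grew less than expected; zero vigor leaves the
    odds of dying unchanged.
    """
    obs = np.asarray(observed_log_agr1, dtype=float)
    pred = np.asarray(predicted_log_agr1, dtype=float)
    if not (np.isfinite(obs).all() and np.isfinite(pred).all()):
        raise ParameterError("vigor inputs must be finite")
    return obs - pred


def linear_predictor_arrays(v, x, hmax, ortho, wd, tough, beta,
                            basis: OntogenyBasis, intercept=None):
    """Mortality linear predictor eta (vectorized core).

    ``beta`` is the effective beta0..beta6 sequence; deselected terms are
    already zero there.  ``x`` must be positive.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ParameterError("ontogenetic stage x = D/DBH95 must be positive")
    b = [float(beta[i]) for i in range(7)]
    eta = (b[0] * np.asarray(v, dtype=float)
           + b[1] * basis.f1(x)
           + b[2] * basis.f2(x)
           + b[3] * np.asarray(hmax, dtype=float)
           + b[4] * np.asarray(ortho, dtype=float)
           + b[5] * np.asarray(wd, dtype=float)
           + b[6] * np.asarray(tough, dtype=float))
    if intercept is not None:
        eta = eta + float(intercept)
    return eta


def mortality_linear_predictor(v: float, dbh_cm: float, traits: TraitVector,
                               params: MortalityParams) -> float:
    """eta for one tree: vigor, ontogeny basis and four trait terms."""
    x = float(dbh_cm) / m_to_cm(traits.dbh95)
    return float(linear_predictor_arrays(
        v, x, traits.hmax, traits.ortho, traits.wd, traits.tough,
        params.beta(), params.basis, params.intercept))


def mortality_probability(eta):
    """Per-census-interval death probability p = logistic(eta)."""
    return expit(np.asarray(eta, dtype=float)) if np.ndim(eta) else float(expit(eta))


def annualized_probability(p, interval_years: float):
    """Annual death rate 1 - (1-p)^(1/dt).  Reporting convenience only;
    the model itself works on the census interval."""
    if interval_years <= 0:
        raise ParameterError("interval_years must be positive")
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** (1.0 / interval_years)


def bernoulli_loglik(eta, died):
    """Sum of Bernoulli log-likelihood terms from the linear predictor.

    Numerically stable via log-sigmoid; eta = +/-inf yields -inf when the
    opposing outcome is observed, never an exception.
    """
    eta = np.asarray(eta, dtype=float)
    sign = np.where(np.asarray(died, dtype=bool), 1.0, -1.0)
    return float(-np.logaddexp(0.0, -sign * eta).sum())
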
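"""Random encounter and staying time (REST) likelihood components.

The REST estimator maps the number of animal passages through a small focal
area of known size (here an equilateral triangle in front of the camera) to
population density:

    D = (N / A) * (E[staying time] / active time)

where N is the passage count, A the focal area, and "active time" is the
camera deployment time multiplied by the fraction of the day the population
is active.  Habitat structure enters through a log-linear model of density on
principal-component scores of the surrounding landscape composition:

    D_i = exp(alpha_0 + sum_e alpha_e * PC_{e,i})     [animals per km^2]

The expected passage count at a camera inverts the density equation, and
counts are modelled as negative binomial (a gamma-mixed Poisson) to absorb
camera-level heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "FocalArea",
    "HabitatDensityParams",
    "M2_PER_KM2",
    "focal_area_from_side",
    "rest_density_point",
    "linear_predictor",
    "expected_count",
    "nb_loglik",
]

#: unit conversion: densities are carried per km^2, focal areas in m^2
M2_PER_KM2 = 1.0e6


@dataclass(frozen=True)
class FocalArea:
    """Focal detection area: an equilateral triangle of given side length."""

    side_m: float
    area_m2: float


@dataclass
class HabitatDensityParams:
    """Log-linear density parameters for one month and age class.

    ``alpha`` is the 5-vector (intercept, PC1..PC4 coefficients); the
    intercept is log density per km^2 at average landscape composition.
    """

    month: str
    age_class: str
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.shape != (5,):
            raise ValueError("alpha must have 5 entries (intercept + 4 PC slopes)")


def focal_area_from_side(side_m: float) -> FocalArea:
    """Area of the equilateral-triangle focal area, (sqrt(3)/4) * side^2."""
    if not side_m > 0:
        raise ValueError(f"side_m must be positive, got {side_m}")
    return FocalArea(side_m=float(side_m), area_m2=float(np.sqrt(3.0) / 4.0 * side_m**2))


def rest_density_point(
    n_passages: float, area_m2: float, mean_stay_s: float, active_time_s: float
) -> float:
    """Point REST density estimate in animals per km^2.

    D = (N / A) * (mean staying time / active time), converted m^-2 -> km^-2.
    """
    if not area_m2 > 0:
        raise ValueError("area_m2 must be positive")
    if not mean_stay_s > 0:
        raise ValueError("mean_stay_s must be positive")
    if not active_time_s > 0:
        raise ValueError("active_time_s must be positive")
    if n_passages < 0:
        raise ValueError("n_passages must be non-negative")
    return (n_passages / area_m2) * (mean_stay_s / active_time_s) * M2_PER_KM2


def linear_predictor(alpha: np.ndarray, pc_scores: np.ndarray) -> np.ndarray:
    """alpha_0 + sum_e alpha_e * PC_e, vectorized over rows of ``pc_scores``."""
    alpha = np.asarray(alpha, dtype=float)
    scores = np.atleast_2d(np.asarray(pc_scores, dtype=float))
    if alpha.size != scores.shape[1] + 1:
        raise ValueError(
            f"alpha has {alpha.size} entries but scores have {scores.shape[1]} axes"
        )
    return alpha[0] + scores @ alpha[1:]


def expected_count(
    alpha: np.ndarray,
    pc_scores: np.ndarray,
    area_m2: float,
    mean_stay_s: float,
    active_time_s: float | np.ndarray,
) -> np.ndarray:
    """Expected passage count mu for cameras with the given PC scores.

    Inverts the REST density equation: with D = exp(linear predictor) in
    animals per km^2,

        mu = D * 1e-6 [m^-2] * area_m2 * active_time_s / mean_stay_s.
    """
    if not area_m2 > 0 or not mean_stay_s > 0:
        raise ValueError("area_m2 and mean_stay_s must be positive")
    active = np.asarray(active_time_s, dtype=float)
    if np.any(active < 0):
        raise ValueError("active_time_s must be non-negative")
    eta = linear_predictor(alpha, pc_scores)
    mu = np.exp(eta) / M2_PER_KM2 * area_m2 * active / mean_stay_s
    return mu if mu.size > 1 else float(mu[0])


def nb_loglik(n_passages, mu, k):
    """Log pmf of the negative binomial with mean mu and gamma shape k.

    Parameterized as a Poisson whose rate is gamma-distributed with shape k
    and mean mu, giving variance mu + mu^2 / k.  Vectorized; returns the
    elementwise log pmf.
    """
    n = np.asarray(n_passages, dtype=float)
    mu = np.asarray(mu, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(n < 0) or np.any(n != np.floor(n)):
        raise ValueError("n_passages must be non-negative integers")
    if np.any(mu <= 0) or np.any(k <= 0):
        raise ValueError("mu and k must be positive")
    return (
        gammaln(n + k)
        - gammaln(k)
        - gammaln(n + 1.0)
        + k * (np.log(k) - np.log(k + mu))
        + n * (np.log(mu) - np.log(k + mu))
    )
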
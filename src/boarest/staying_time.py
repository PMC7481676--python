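"""Parametric models for focal-area staying time.

Staying time — how long an animal remains inside the camera's focal area on
one passage — is inversely proportional to movement speed and supplies the
numerator-time term of the REST density equation.  Candidate families are
exponential, gamma, lognormal and Weibull, each optionally extended with a
lognormal camera-station random effect (a per-camera multiplicative scale
factor exp(u_j), u_j ~ Normal(0, tau^2)).  Each family is fitted by MCMC with
weakly informative Normal(0, 10) priors on its unconstrained (log-scale)
parameters, the fit is scored by WAIC, and the minimum-WAIC candidate is
selected (ties broken toward fewer parameters).

The quantity the density model consumes is the analytic mean of the fitted
family; its posterior draws are retained so staying-time uncertainty can
propagate into the joint model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .mcmc import Block, WaicResult, run_blocked_metropolis, waic

__all__ = [
    "FAMILIES",
    "Family",
    "StayingTimeModel",
    "family_loglik",
    "family_mean",
    "fit_family",
    "select_best",
    "sweep_families",
    "expected_staying_time",
]


@dataclass(frozen=True)
class Family:
    """A staying-time family on unconstrained parameters (log scales)."""

    name: str
    n_params: int
    param_names: tuple[str, ...]


FAMILIES: dict[str, Family] = {
    "exponential": Family("exponential", 1, ("log_rate",)),
    "gamma": Family("gamma", 2, ("log_shape", "log_rate")),
    "lognormal": Family("lognormal", 2, ("mu", "log_sigma")),
    "weibull": Family("weibull", 2, ("log_shape", "log_scale")),
}


def family_loglik(family: str, times_s: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Pointwise log density of ``times_s`` under the family.

    ``params`` are unconstrained: positive parameters enter as logs and the
    lognormal location ``mu`` as itself.
    """
    t = np.asarray(times_s, dtype=float)
    if np.any(t <= 0):
        raise ValueError("staying times must be positive")
    p = np.asarray(params, dtype=float)
    logt = np.log(t)
    if family == "exponential":
        (log_rate,) = p
        return log_rate - np.exp(log_rate) * t
    if family == "gamma":
        log_shape, log_rate = p
        a, b = np.exp(log_shape), np.exp(log_rate)
        return a * log_rate - gammaln(a) + (a - 1.0) * logt - b * t
    if family == "lognormal":
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        return (
            -logt
            - log_sigma
            - 0.5 * np.log(2.0 * np.pi)
            - 0.5 * ((logt - mu) / sigma) ** 2
        )
    if family == "weibull":
        log_shape, log_scale = p
        k = np.exp(log_shape)
        z = np.exp(logt - log_scale)
        return log_shape - log_scale + (k - 1.0) * (logt - log_scale) - z**k
    raise ValueError(f"unknown staying-time family {family!r}")


def family_mean(family: str, params: np.ndarray) -> float:
    """Analytic mean of the family at unconstrained parameters ``params``."""
    p = np.asarray(params, dtype=float)
    if family == "exponential":
        return float(np.exp(-p[0]))
    if family == "gamma":
        return float(np.exp(p[0] - p[1]))
    if family == "lognormal":
        mu, sigma = p[0], np.exp(p[1])
        return float(np.exp(mu + 0.5 * sigma**2))
    if family == "weibull":
        k = np.exp(p[0])
        mean = np.exp(p[1]) * np.exp(gammaln(1.0 + 1.0 / k))
        if not np.isfinite(mean):
            raise ValueError("Weibull mean undefined at the fitted parameters")
        return float(mean)
    raise ValueError(f"unknown staying-time family {family!r}")


def _init_params(family: str, t: np.ndarray) -> np.ndarray:
    m, v = t.mean(), max(t.var(ddof=1), 1e-12)
    if family == "exponential":
        return np.array([-np.log(m)])
    if family == "gamma":
        shape = max(m**2 / v, 1e-3)
        return np.log([shape, shape / m])
    if family == "lognormal":
        logt = np.log(t)
        return np.array([logt.mean(), np.log(max(logt.std(ddof=1), 1e-6))])
    if family == "weibull":
        return np.array([0.0, np.log(m)])
    raise ValueError(f"unknown staying-time family {family!r}")


@dataclass
class StayingTimeModel:
    """A fitted staying-time model for one data subset."""

    family: str
    with_camera_random_effect: bool
    param_draws: np.ndarray = field(repr=False)  # (n_draws, n_params)
    mean_draws: np.ndarray = field(repr=False)  # posterior draws of the mean
    waic: float
    waic_detail: WaicResult = field(repr=False)
    expected_staying_time_s: float
    n_obs: int
    data_fingerprint: str
    month: str | None = None
    age_class: str | None = None
    tau_draws: np.ndarray | None = field(default=None, repr=False)


def _fingerprint(times_s: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(times_s, dtype=float).tobytes()).hexdigest()


def fit_family(
    times_s: np.ndarray,
    family: str,
    camera_ids: np.ndarray | None = None,
    random_effect: bool = False,
    *,
    prior_sd: float = 10.0,
    iterations: int = 3000,
    burn_in: int = 1000,
    thin: int = 2,
    chains: int = 2,
    seed: int = 0,
    month: str | None = None,
    age_class: str | None = None,
) -> StayingTimeModel:
    """Bayesian fit of one candidate family to staying times (seconds).

    With ``random_effect``, each camera j gets a multiplicative scale
    exp(u_j): the observation density is f(t * exp(-u_j)) * exp(-u_j) with
    u_j ~ Normal(0, tau^2) and tau ~ half-Normal(1).  WAIC is computed from
    the pointwise log-likelihood draws (conditional on u).
    """
    t = np.asarray(times_s, dtype=float)
    if t.ndim != 1 or t.size < 3:
        raise ValueError("need at least 3 staying times")
    if np.any(t <= 0):
        raise ValueError("staying times must be positive")
    fam = FAMILIES.get(family)
    if fam is None:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(FAMILIES)}")
    if random_effect:
        if camera_ids is None:
            raise ValueError("random_effect=True requires camera_ids")
        cams, cam_idx = np.unique(np.asarray(camera_ids), return_inverse=True)
        n_cam = cams.size
    else:
        cam_idx, n_cam = None, 0

    npar = fam.n_params
    dim = npar + (1 + n_cam if random_effect else 0)
    x0 = np.zeros(dim)
    x0[:npar] = _init_params(family, t)
    if random_effect:
        x0[npar] = np.log(0.3)  # log tau

    def pointwise_ll(x: np.ndarray) -> np.ndarray:
        if random_effect:
            u = x[npar + 1 :][cam_idx]
            return family_loglik(family, t * np.exp(-u), x[:npar]) - u
        return family_loglik(family, t, x[:npar])

    def logp_params(x: np.ndarray) -> float:
        lp = -0.5 * np.sum((x[:npar] / prior_sd) ** 2)
        return lp + float(pointwise_ll(x).sum())

    blocks = [Block("params", np.arange(npar), logp_params, init_sd=0.1)]

    if random_effect:

        def logp_re(x: np.ndarray) -> float:
            log_tau = x[npar]
            tau = np.exp(log_tau)
            u = x[npar + 1 :]
            # half-Normal(1) prior on tau with log-scale Jacobian
            lp = -0.5 * tau**2 + log_tau
            lp += -0.5 * np.sum((u / tau) ** 2) - n_cam * log_tau
            return lp + float(pointwise_ll(x).sum())

        blocks.append(
            Block("re", np.arange(npar, dim), logp_re, init_sd=0.1)
        )

    res = run_blocked_metropolis(
        blocks, x0, iterations=iterations, burn_in=burn_in, thin=thin,
        chains=chains, seed=seed,
    )
    flat = res.draws.reshape(-1, dim)
    param_draws = flat[:, :npar]
    ll_draws = np.stack([pointwise_ll(x) for x in flat])
    w = waic(ll_draws)
    mean_draws = np.array([family_mean(family, p) for p in param_draws])
    return StayingTimeModel(
        family=family,
        with_camera_random_effect=random_effect,
        param_draws=param_draws,
        mean_draws=mean_draws,
        waic=w.waic,
        waic_detail=w,
        expected_staying_time_s=float(mean_draws.mean()),
        n_obs=t.size,
        data_fingerprint=_fingerprint(t),
        month=month,
        age_class=age_class,
        tau_draws=np.exp(flat[:, npar]) if random_effect else None,
    )


def _complexity(model: StayingTimeModel) -> int:
    return FAMILIES[model.family].n_params + (1 if model.with_camera_random_effect else 0)


def select_best(candidates: list[StayingTimeModel]) -> StayingTimeModel:
    """Minimum-WAIC candidate; exact ties broken toward fewer parameters."""
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate models to select among")
    prints = {m.data_fingerprint for m in candidates}
    if len(prints) != 1:
        raise ValueError("candidate models were fitted on different data")
    return min(candidates, key=lambda m: (m.waic, _complexity(m)))


def sweep_families(
    times_s: np.ndarray,
    camera_ids: np.ndarray | None = None,
    *,
    families: list[str] | None = None,
    random_effects: tuple[bool, ...] = (False, True),
    seed: int = 0,
    **fit_kwargs,
) -> list[StayingTimeModel]:
    """Fit every (family, random-effect) candidate on the same data."""
    families = list(FAMILIES) if families is None else families
    out = []
    s = seed
    for re_flag in random_effects:
        if re_flag and camera_ids is None:
            continue
        for fam in families:
            out.append(
                fit_family(
                    times_s, fam, camera_ids, re_flag, seed=s, **fit_kwargs
                )
            )
            s += 1
    return out


def expected_staying_time(model: StayingTimeModel) -> float:
    """Posterior mean of the family's analytic mean staying time (seconds)."""
    return model.expected_staying_time_s
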
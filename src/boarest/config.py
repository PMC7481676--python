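"""Study configuration: geometry, months, MCMC settings and priors."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["ConfigError", "McmcConfig", "PriorConfig", "StudyConfig", "default_months"]


class ConfigError(ValueError):
    pass


def default_months(start: str = "2018-06", n: int = 12) -> list[str]:
    """Consecutive month labels 'YYYY-MM' starting at ``start``."""
    import pandas as pd

    return [str(p) for p in pd.period_range(start, periods=n, freq="M")]


@dataclass
class McmcConfig:
    iterations: int = 50_000
    burn_in: int = 10_000
    thin: int = 20
    chains: int = 3
    seed: int = 1


@dataclass
class PriorConfig:
    alpha_low: float = -3.0
    alpha_high: float = 3.0
    catchability_low: float = 0.0
    catchability_high: float = 1.0
    # half-Cauchy scale on 1/sqrt(k) for the negative-binomial dispersion k
    dispersion_half_cauchy_scale: float = 5.0
    stay_prior_sd: float = 10.0


@dataclass
class StudyConfig:
    focal_side_m: float = 1.9
    buffer_radius_m: float = 500.0  # metadata: buffer used to derive compositions
    n_pc_axes: int = 4
    months: list[str] = field(default_factory=default_months)
    age_classes: list[str] = field(default_factory=lambda: ["adult", "juvenile"])
    juvenile_months: list[str] | None = None  # None: wherever data suffice
    activity_min_detections: int = 10
    activity_fixed_kappa: float | None = None
    stay_families: list[str] = field(
        default_factory=lambda: ["exponential", "gamma", "lognormal", "weibull"]
    )
    stay_random_effects: bool = True  # include RE variants in the WAIC sweep
    stay_min_n: int = 10
    stay_mode: str = "joint"  # "joint": sample stay params in the model; "plugin": fix
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    priors: PriorConfig = field(default_factory=PriorConfig)

    def validate(self) -> "StudyConfig":
        if not self.focal_side_m > 0:
            raise ConfigError("focal_side_m must be positive")
        if self.n_pc_axes < 1:
            raise ConfigError("n_pc_axes must be >= 1")
        if not self.months:
            raise ConfigError("months must be non-empty")
        m = self.mcmc
        if not (m.iterations > m.burn_in >= 0):
            raise ConfigError("mcmc: need iterations > burn_in >= 0")
        if m.thin < 1 or m.chains < 1:
            raise ConfigError("mcmc: thin and chains must be >= 1")
        p = self.priors
        if not p.alpha_low < p.alpha_high:
            raise ConfigError("priors: alpha_low must be < alpha_high")
        if (p.alpha_low, p.alpha_high) != (-3.0, 3.0):
            import warnings

            warnings.warn(
                "habitat-coefficient prior widened beyond the reference "
                f"Uniform(-3, 3) to Uniform({p.alpha_low}, {p.alpha_high})",
                stacklevel=2,
            )
        if not (0 <= p.catchability_low < p.catchability_high <= 1):
            raise ConfigError("priors: need 0 <= catchability_low < catchability_high <= 1")
        if self.stay_mode not in ("joint", "plugin"):
            raise ConfigError("stay_mode must be 'joint' or 'plugin'")
        unknown = set(self.stay_families) - {"exponential", "gamma", "lognormal", "weibull"}
        if unknown:
            raise ConfigError(f"unknown staying-time families: {sorted(unknown)}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mcmc = McmcConfig(**raw.pop("mcmc", {}))
        priors = PriorConfig(**raw.pop("priors", {}))
        try:
            cfg = cls(mcmc=mcmc, priors=priors, **raw)
        except TypeError as exc:
            raise ConfigError(f"bad config key: {exc}") from exc
        return cfg.validate()

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
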
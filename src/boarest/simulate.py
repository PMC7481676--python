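"""Generative simulator for complete synthetic camera + harvest studies.

Draws every table the fitting pipeline consumes from the model's own
generative structure, with known ground truth, so parameter recovery can be
tested end to end without field data:

* landscape compositions from a two-component Dirichlet mixture
  (forest-dominated vs. mosaic sites), giving realistic correlations among
  the six land-use classes;
* camera passage counts per month and age class from the habitat-dependent
  REST expectation, negative-binomially dispersed (gamma-Poisson);
* per-passage staying times from the true parametric family (lognormal by
  default) and detection timestamps from the true von Mises circadian
  activity density;
* monthly unit harvests from the Poisson catch-effort relation with true
  catchabilities, using trap counts drawn from a negative binomial
  calibrated to plausible municipal effort.

The default scenario mirrors the study scale (180 cameras, 897 one-km^2
cells, 33 management units, 12 months); a "small" preset (30/100/6/3) keeps
test runtimes short.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import i0

from .config import StudyConfig, default_months
from .landscape import LANDSCAPE_CLASSES, PcaBasis, fit_pca, project
from .management import TRAP_TYPES
from .rest import expected_count, focal_area_from_side
from .staying_time import family_mean

__all__ = [
    "SCENARIOS",
    "TruthBundle",
    "Landscape",
    "SimulatedStudy",
    "default_truth",
    "simulate_landscape",
    "simulate_camera_data",
    "simulate_harvest",
    "simulate_study",
    "simulate_scenario",
]

SCENARIOS = {
    "study": dict(n_sites=180, n_cells=897, n_units=33, n_months=12),
    "small": dict(n_sites=30, n_cells=100, n_units=6, n_months=3),
}

# Dirichlet concentrations (x 6 classes + remainder) for the two site kinds
_FOREST_ALPHA = np.array([30.0, 18.0, 4.0, 3.0, 2.5, 1.5, 6.0])
_MOSAIC_ALPHA = np.array([8.0, 5.0, 22.0, 4.0, 9.0, 10.0, 10.0])
_FOREST_FRACTION = 0.55


@dataclass
class TruthBundle:
    """All generating parameters of a synthetic study."""

    months: list[str]
    juvenile_months: list[str]
    alpha: dict[tuple[str, str], np.ndarray]  # (month, age) -> 5-vector
    nb_k: dict[tuple[str, str], float]
    stay_family: str
    stay_params: dict[tuple[str, str], np.ndarray]  # unconstrained params
    activity_vm: dict[tuple[str, str], tuple[float, float]]  # (peak hour, kappa)
    catchability: dict[tuple[str, str], float]  # (month, trap type)

    def ages_in_month(self, month: str) -> list[str]:
        ages = ["adult"]
        if month in self.juvenile_months:
            ages.append("juvenile")
        return ages

    def activity_proportion(self, month: str, age: str) -> float:
        """True daily activity proportion of a von Mises rhythm: I0(k)/e^k."""
        _, kappa = self.activity_vm[(month, age)]
        return float(i0(kappa) * np.exp(-kappa)) if kappa > 0 else 1.0

    def mean_stay(self, month: str, age: str) -> float:
        return family_mean(self.stay_family, self.stay_params[(month, age)])


def default_truth(
    months: list[str] | None = None,
    juvenile_months: list[str] | None = None,
) -> TruthBundle:
    """Ground truth echoing the study system's magnitudes.

    Adult density around exp(2) ~ 7.4 km^-2 with mild seasonal variation;
    habitat slopes negative on PC1/PC2 and positive on PC3/PC4; lognormal
    staying times with mean ~8 s; nocturnal activity (~40% of the day);
    catchabilities 0.02 (box) and 0.012 (snare).
    """
    if months is None:
        months = default_months()
    if juvenile_months is None:
        juvenile_months = months[: max(1, len(months) // 2)]
    alpha, nb_k, stay_params, activity_vm, catchability = {}, {}, {}, {}, {}
    slopes = np.array([-0.3, -0.2, 0.4, 0.15])
    for j, m in enumerate(months):
        season = np.sin(2.0 * np.pi * j / max(len(months), 2))
        for age in ["adult", "juvenile"]:
            if age == "juvenile" and m not in juvenile_months:
                continue
            a0 = (2.0 if age == "adult" else 1.2) + 0.3 * season
            alpha[(m, age)] = np.concatenate([[a0], slopes * (1.0 + 0.2 * season)])
            nb_k[(m, age)] = 1.0
            stay_params[(m, age)] = np.array(
                [1.8 if age == "adult" else 1.6, np.log(0.7)]
            )
            activity_vm[(m, age)] = (22.0, 1.2) if age == "adult" else (14.0, 0.8)
        catchability[(m, "box")] = 0.02
        catchability[(m, "snare")] = 0.012
    return TruthBundle(
        months=list(months),
        juvenile_months=list(juvenile_months),
        alpha=alpha,
        nb_k=nb_k,
        stay_family="lognormal",
        stay_params=stay_params,
        activity_vm=activity_vm,
        catchability=catchability,
    )


@dataclass
class Landscape:
    sites: pd.DataFrame  # site_id + class percentages
    cells: pd.DataFrame  # cell_id + class percentages
    units: pd.DataFrame  # cell_id, unit_id, forest_area_km2


def _draw_compositions(n: int, rng: np.random.Generator) -> np.ndarray:
    kind = rng.uniform(size=n) < _FOREST_FRACTION
    comp = np.empty((n, 7))
    n_forest = int(kind.sum())
    if n_forest:
        comp[kind] = rng.dirichlet(_FOREST_ALPHA, size=n_forest)
    if n - n_forest:
        comp[~kind] = rng.dirichlet(_MOSAIC_ALPHA, size=n - n_forest)
    return 100.0 * comp[:, :6]  # drop the "other" remainder


def simulate_landscape(
    n_sites: int = 180, n_cells: int = 897, n_units: int = 33, seed: int = 0
) -> Landscape:
    """Site and cell compositions plus a contiguous cell -> unit partition."""
    if min(n_sites, n_cells, n_units) < 1:
        raise ValueError("counts must be >= 1")
    if n_units > n_cells:
        raise ValueError("cannot have more units than cells")
    rng = np.random.default_rng(seed)
    sites = pd.DataFrame(_draw_compositions(n_sites, rng), columns=LANDSCAPE_CLASSES)
    sites.insert(0, "site_id", [f"cam{i:03d}" for i in range(n_sites)])
    cells = pd.DataFrame(_draw_compositions(n_cells, rng), columns=LANDSCAPE_CLASSES)
    cells.insert(0, "cell_id", [f"cell{i:04d}" for i in range(n_cells)])
    # contiguous striping of the (row-major) cell grid into units
    unit_of = np.floor(np.arange(n_cells) * n_units / n_cells).astype(int)
    forest = cells[["broadleaf", "conifer", "bamboo"]].sum(axis=1) / 100.0
    units = pd.DataFrame(
        {
            "cell_id": cells["cell_id"],
            "unit_id": [f"u{u:02d}" for u in unit_of],
            "forest_area_km2": forest.to_numpy(),
        }
    )
    return Landscape(sites=sites, cells=cells, units=units)


def _month_span(month: str) -> tuple[pd.Timestamp, int]:
    start = pd.Period(month, freq="M").start_time
    n_days = pd.Period(month, freq="M").days_in_month
    return start, n_days


def simulate_camera_data(
    truth: TruthBundle,
    site_scores: pd.DataFrame,
    month: str,
    seed: int,
    *,
    focal_side_m: float = 1.9,
    deployment_s_per_camera: float | None = None,
) -> pd.DataFrame:
    """Detection rows (one per passage) for one month, all age classes.

    Counts are gamma-Poisson (negative binomial) around the REST expectation;
    each passage gets a staying time from the true family and a timestamp
    whose time of day follows the true von Mises activity density.
    """
    if month not in truth.months:
        raise ValueError(f"month {month!r} missing from the truth bundle")
    rng = np.random.default_rng(seed)
    area = focal_area_from_side(focal_side_m).area_m2
    start, n_days = _month_span(month)
    deploy_s = (
        n_days * 86400.0 if deployment_s_per_camera is None else deployment_s_per_camera
    )
    rows = []
    for age in truth.ages_in_month(month):
        alpha = truth.alpha[(month, age)]
        k = truth.nb_k[(month, age)]
        p_act = truth.activity_proportion(month, age)
        mean_stay = truth.mean_stay(month, age)
        mu = np.atleast_1d(
            expected_count(
                alpha, site_scores.to_numpy(), area, mean_stay, deploy_s * p_act
            )
        )
        lam = rng.gamma(k, mu / k)
        counts = rng.poisson(lam)
        peak_h, kappa = truth.activity_vm[(month, age)]
        mu_p, sig_p = truth.stay_params[(month, age)]
        for cam, n in zip(site_scores.index, counts):
            if n == 0:
                continue
            theta = rng.vonmises(0.0, kappa, size=n) if kappa > 0 else rng.uniform(
                -np.pi, np.pi, size=n
            )
            tod_h = (theta / (2.0 * np.pi) * 24.0 + peak_h) % 24.0
            days = rng.integers(0, n_days, size=n)
            stays = rng.lognormal(mu_p, np.exp(sig_p), size=n)
            for d, h, s in zip(days, tod_h, stays):
                ts = start + pd.Timedelta(days=int(d), seconds=float(h) * 3600.0)
                rows.append(
                    {
                        "camera_id": cam,
                        "timestamp": ts.floor("s"),
                        "age_class": age,
                        "staying_time_s": round(float(s), 2),
                    }
                )
    df = pd.DataFrame(rows, columns=["camera_id", "timestamp", "age_class", "staying_time_s"])
    return df.sort_values(["camera_id", "timestamp"]).reset_index(drop=True)


def true_unit_densities(
    truth: TruthBundle, cell_scores: pd.DataFrame, units: pd.DataFrame, month: str
) -> pd.Series:
    """Ground-truth forest-weighted unit densities (ages summed) for a month."""
    merged = units.merge(
        cell_scores, left_on="cell_id", right_index=True, validate="one_to_one"
    )
    pc_cols = [c for c in merged.columns if c.startswith("PC")]
    total = np.zeros(len(merged))
    for age in truth.ages_in_month(month):
        alpha = truth.alpha[(month, age)]
        total += np.exp(alpha[0] + merged[pc_cols].to_numpy() @ alpha[1:])
    w = merged["forest_area_km2"].to_numpy()
    num = pd.Series(total * w, index=merged["unit_id"]).groupby(level=0).sum()
    den = merged.groupby("unit_id")["forest_area_km2"].sum()
    return num / den


def simulate_harvest(
    truth: TruthBundle,
    unit_density: pd.Series,
    month: str,
    seed: int,
    *,
    trap_means: dict[str, float] | None = None,
    trap_k: float = 5.0,
    trap_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Monthly harvest rows: Poisson catches from the catch-effort relation.

    Trap counts per unit and type are negative binomial around plausible
    municipal effort unless an explicit ``trap_table`` (unit_id, trap_type,
    n_traps) is supplied.
    """
    rng = np.random.default_rng(seed)
    trap_means = trap_means or {"box": 20.0, "snare": 15.0}
    rows = []
    for trap in TRAP_TYPES:
        c = truth.catchability[(month, trap)]
        for u, dens in unit_density.items():
            if trap_table is not None:
                sel = (trap_table["unit_id"] == u) & (trap_table["trap_type"] == trap)
                n_traps = int(trap_table.loc[sel, "n_traps"].sum())
            else:
                lam_t = rng.gamma(trap_k, trap_means[trap] / trap_k)
                n_traps = int(rng.poisson(lam_t))
            if n_traps < 0:
                raise ValueError("n_traps must be non-negative")
            lam = c * n_traps * float(dens)
            catch = int(rng.poisson(lam)) if n_traps > 0 else 0
            rows.append(
                {
                    "unit_id": u, "month": month, "trap_type": trap,
                    "n_traps": n_traps, "n_trapped": catch,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SimulatedStudy:
    truth: TruthBundle
    landscape: Landscape
    basis: PcaBasis
    detections: pd.DataFrame
    deployments: pd.DataFrame
    harvest: pd.DataFrame
    site_scores: pd.DataFrame = field(repr=False, default=None)
    cell_scores: pd.DataFrame = field(repr=False, default=None)

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "detections": self.detections,
            "deployments": self.deployments,
            "sites": self.landscape.sites,
            "cells": self.landscape.cells,
            "harvest": self.harvest,
            "units": self.landscape.units,
        }


def simulate_study(
    truth: TruthBundle,
    landscape: Landscape,
    seed: int,
    *,
    focal_side_m: float = 1.9,
    deployment_s_per_camera: float | None = None,
    n_pc_axes: int = 4,
) -> SimulatedStudy:
    """Full synthetic study: detections, deployments and harvest tables."""
    ss = np.random.SeedSequence(seed)
    month_seeds = ss.generate_state(2 * len(truth.months)) % (2**31)
    basis = fit_pca(landscape.sites, n_axes=n_pc_axes)
    site_scores = basis.site_scores
    cell_scores = project(basis, landscape.cells)

    det_parts, harv_parts, deploy_rows = [], [], []
    for j, m in enumerate(truth.months):
        det_parts.append(
            simulate_camera_data(
                truth, site_scores, m, int(month_seeds[2 * j]),
                focal_side_m=focal_side_m,
                deployment_s_per_camera=deployment_s_per_camera,
            )
        )
        du = true_unit_densities(truth, cell_scores, landscape.units, m)
        harv_parts.append(
            simulate_harvest(truth, du, m, int(month_seeds[2 * j + 1]))
        )
    first = pd.Period(truth.months[0], freq="M").start_time
    last = (pd.Period(truth.months[-1], freq="M") + 1).start_time
    for cam in landscape.sites["site_id"]:
        deploy_rows.append({"camera_id": cam, "start": first, "end": last})

    return SimulatedStudy(
        truth=truth,
        landscape=landscape,
        basis=basis,
        detections=pd.concat(det_parts, ignore_index=True),
        deployments=pd.DataFrame(deploy_rows),
        harvest=pd.concat(harv_parts, ignore_index=True),
        site_scores=site_scores,
        cell_scores=cell_scores,
    )


def simulate_scenario(
    preset: str = "small",
    seed: int = 0,
    *,
    months: list[str] | None = None,
    juvenile_months: list[str] | None = None,
    **overrides,
) -> SimulatedStudy:
    """Simulate a named scenario ("study" or "small") end to end."""
    if preset not in SCENARIOS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(SCENARIOS)}")
    params = dict(SCENARIOS[preset])
    params.update({k: v for k, v in overrides.items() if k in params})
    if months is None:
        months = default_months(n=params["n_months"])
    truth = default_truth(months, juvenile_months)
    landscape = simulate_landscape(
        params["n_sites"], params["n_cells"], params["n_units"], seed=seed
    )
    sim_kwargs = {k: v for k, v in overrides.items() if k not in params}
    return simulate_study(truth, landscape, seed=seed + 1, **sim_kwargs)


def study_config_for(
    truth: TruthBundle, *, mcmc=None, stay_families: list[str] | None = None
) -> StudyConfig:
    """A StudyConfig matched to a simulated study's months and age structure."""
    cfg = StudyConfig(
        months=list(truth.months),
        juvenile_months=list(truth.juvenile_months),
    )
    if stay_families is not None:
        cfg.stay_families = stay_families
        cfg.stay_random_effects = False
    if mcmc is not None:
        cfg.mcmc = mcmc
    return cfg.validate()
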
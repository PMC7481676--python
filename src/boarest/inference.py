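"""Joint hierarchical model: REST counts + staying times + catch-effort harvest.

The posterior ties together, per month m and age class a:

* passage counts  n_{i,m,a} ~ NegBin(mu_{i,m,a}, k_{m,a}) with
  mu = exp(alpha_0 + sum_e alpha_e PC_{e,i}) * 1e-6 * focal area *
       deployment_s * activity proportion / E[staying time];
* measured staying times  t ~ the selected parametric family (its parameters
  are sampled jointly, so staying-time uncertainty propagates);
* monthly unit catches  y_{u,m,t} ~ Poisson(c_{m,t} * traps_{u,m,t} * D_{u,m})
  where D_{u,m} is the forest-area-weighted mean over the unit's 1 km^2 cells
  of exp(alpha_0 + sum_e alpha_e PC_{e,c}), summed over the age classes
  modelled in that month.

Priors: alpha ~ Uniform(-3, 3) (hard constraint), catchability ~ Uniform(0,1),
a half-Cauchy on 1 / sqrt(k) for the count dispersion, Normal(0, 10) on the
unconstrained staying-time parameters.  The daily activity proportion enters
as a plug-in point estimate.  Sampling is by the package's blocked adaptive
Metropolis sampler; months factorize, so blocks are (month x age) parameter
vectors plus one catchability pair per month with harvest data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import staying_time as st
from .activity import ActivityEstimate, activity_schedule
from .config import StudyConfig
from .landscape import PcaBasis, fit_pca, project
from .management import TRAP_TYPES
from .mcmc import Block, run_blocked_metropolis, split_rhat, summarize_draws
from .rest import focal_area_from_side, nb_loglik

__all__ = [
    "CountBlock",
    "CellBlock",
    "HarvestBlock",
    "StudyData",
    "JointModel",
    "PosteriorResult",
    "build_study_data",
    "build_joint_model",
    "run_mcmc",
    "rhat",
    "summarize_area_density",
    "summarize_unit_densities",
    "run_fit",
    "FitResult",
]

rhat = split_rhat  # convergence diagnostic re-exported at the model surface


@dataclass
class CountBlock:
    camera_ids: np.ndarray
    n: np.ndarray  # passage counts
    scores: np.ndarray  # (n_cam, n_axes)
    active_s: np.ndarray  # deployment seconds x activity proportion


@dataclass
class CellBlock:
    cell_ids: np.ndarray
    scores: np.ndarray  # (n_cells, n_axes)
    forest_km2: np.ndarray
    unit_codes: np.ndarray  # int index into unit_ids
    unit_ids: list[str]


@dataclass
class HarvestBlock:
    unit_idx: np.ndarray
    trap_idx: np.ndarray  # index into TRAP_TYPES
    n_traps: np.ndarray
    n_trapped: np.ndarray


@dataclass
class StudyData:
    months: list[str]
    focal_area_m2: float
    counts: dict[tuple[str, str], CountBlock]
    stay: dict[tuple[str, str], np.ndarray]
    stay_family: dict[str, str]  # per age class
    activity: dict[tuple[str, str], float]
    cells: CellBlock | None
    harvest: dict[str, HarvestBlock]
    stay_plugin: dict[tuple[str, str], float] = field(default_factory=dict)

    def ages_in_month(self, month: str) -> list[str]:
        return [a for (m, a) in self.counts if m == month]


# ---------------------------------------------------------------------------
# data assembly


def monthly_deployment_seconds(
    deployments: pd.DataFrame, months: list[str]
) -> pd.DataFrame:
    """Seconds each camera was active in each month (camera x month)."""
    cams = deployments["camera_id"].unique()
    out = pd.DataFrame(0.0, index=pd.Index(cams, name="camera_id"), columns=months)
    for m in months:
        m_start = pd.Period(m, freq="M").start_time
        m_end = (pd.Period(m, freq="M") + 1).start_time
        lo = deployments["start"].clip(lower=m_start)
        hi = deployments["end"].clip(upper=m_end)
        secs = (hi - lo).dt.total_seconds().clip(lower=0.0)
        by_cam = secs.groupby(deployments["camera_id"]).sum()
        out.loc[by_cam.index, m] = by_cam
    return out


def build_study_data(
    detections: pd.DataFrame,
    deployments: pd.DataFrame,
    sites: pd.DataFrame,
    cells: pd.DataFrame,
    harvest: pd.DataFrame,
    units: pd.DataFrame,
    config: StudyConfig,
    *,
    basis: PcaBasis | None = None,
    stay_sweep_kwargs: dict | None = None,
) -> tuple[StudyData, PcaBasis, dict]:
    """Assemble validated tables into the model's data blocks.

    Returns the study data, the fitted landscape PCA basis and an ``extras``
    dict holding the activity estimates and the staying-time WAIC sweep.
    """
    config.validate()
    months = list(config.months)
    if basis is None:
        basis = fit_pca(sites, n_axes=config.n_pc_axes)
    site_scores = basis.site_scores
    cell_scores = project(basis, cells)

    effort = monthly_deployment_seconds(deployments, months)
    det = detections.copy()
    det["month"] = pd.to_datetime(det["timestamp"]).dt.strftime("%Y-%m")

    acts = activity_schedule(
        det,
        months,
        config.age_classes,
        min_detections=config.activity_min_detections,
        bandwidth=config.activity_fixed_kappa,
    )

    # staying-time data per (month, age) and pooled per age for family choice
    stay_rows = det[det["staying_time_s"].notna()]
    stay: dict[tuple[str, str], np.ndarray] = {}
    for (m, a), grp in stay_rows.groupby(["month", "age_class"]):
        if m in months:
            stay[(m, a)] = grp["staying_time_s"].to_numpy(dtype=float)

    stay_family: dict[str, str] = {}
    sweeps: dict[str, list[st.StayingTimeModel]] = {}
    sweep_kwargs = dict(
        iterations=2000, burn_in=500, thin=2, chains=2,
        prior_sd=config.priors.stay_prior_sd,
    )
    sweep_kwargs.update(stay_sweep_kwargs or {})
    for a in config.age_classes:
        pooled = stay_rows[stay_rows["age_class"] == a]
        times = pooled["staying_time_s"].to_numpy(dtype=float)
        if times.size < config.stay_min_n:
            continue
        if len(config.stay_families) == 1 and not config.stay_random_effects:
            stay_family[a] = config.stay_families[0]
            continue
        models = st.sweep_families(
            times,
            pooled["camera_id"].to_numpy(),
            families=config.stay_families,
            random_effects=(False, True) if config.stay_random_effects else (False,),
            **sweep_kwargs,
        )
        best = st.select_best(models)
        stay_family[a] = best.family
        sweeps[a] = models

    # which (month, age) cells are modelled
    counts: dict[tuple[str, str], CountBlock] = {}
    stay_plugin: dict[tuple[str, str], float] = {}
    for a in config.age_classes:
        if a not in stay_family:
            continue
        for m in months:
            if a == "juvenile" and config.juvenile_months is not None and m not in config.juvenile_months:
                continue
            if (m, a) not in stay or stay[(m, a)].size < config.stay_min_n:
                continue
            if (m, a) not in acts:
                continue
            cams = effort.index[effort[m] > 0]
            cams = [c for c in cams if c in site_scores.index]
            if not cams:
                continue
            key = (m, a)
            sub = det[(det["month"] == m) & (det["age_class"] == a)]
            n = sub.groupby("camera_id").size().reindex(cams, fill_value=0)
            counts[key] = CountBlock(
                camera_ids=np.asarray(cams),
                n=n.to_numpy(dtype=int),
                scores=site_scores.loc[cams].to_numpy(),
                active_s=effort.loc[cams, m].to_numpy()
                * acts[key].activity_proportion,
            )
            if config.stay_mode == "plugin":
                model = st.fit_family(
                    stay[key], stay_family[a], seed=abs(hash(key)) % (2**31),
                    **{k: v for k, v in sweep_kwargs.items() if k != "prior_sd"},
                    prior_sd=config.priors.stay_prior_sd,
                )
                stay_plugin[key] = model.expected_staying_time_s

    # cells + harvest
    cell_tbl = cells.merge(units, on="cell_id", validate="one_to_one")
    unit_ids = sorted(cell_tbl["unit_id"].unique())
    unit_code = {u: i for i, u in enumerate(unit_ids)}
    cb = CellBlock(
        cell_ids=cell_tbl["cell_id"].to_numpy(),
        scores=cell_scores.loc[cell_tbl["cell_id"]].to_numpy(),
        forest_km2=cell_tbl["forest_area_km2"].to_numpy(dtype=float),
        unit_codes=cell_tbl["unit_id"].map(unit_code).to_numpy(),
        unit_ids=unit_ids,
    )

    harvest_blocks: dict[str, HarvestBlock] = {}
    for m, grp in harvest.groupby("month"):
        if m not in months:
            continue
        unknown = set(grp["unit_id"]) - set(unit_ids)
        if unknown:
            raise ValueError(f"harvest refers to unknown units: {sorted(unknown)}")
        harvest_blocks[str(m)] = HarvestBlock(
            unit_idx=grp["unit_id"].map(unit_code).to_numpy(),
            trap_idx=grp["trap_type"].map(TRAP_TYPES.index).to_numpy(),
            n_traps=grp["n_traps"].to_numpy(dtype=float),
            n_trapped=grp["n_trapped"].to_numpy(dtype=float),
        )

    data = StudyData(
        months=months,
        focal_area_m2=focal_area_from_side(config.focal_side_m).area_m2,
        counts=counts,
        stay=stay,
        stay_family=stay_family,
        activity={k: v.activity_proportion for k, v in acts.items()},
        cells=cb,
        harvest=harvest_blocks,
        stay_plugin=stay_plugin,
    )
    extras = {"activity": acts, "stay_sweeps": sweeps}
    return data, basis, extras


# ---------------------------------------------------------------------------
# joint model


@dataclass
class JointModel:
    data: StudyData
    config: StudyConfig
    names: list[str]
    x0: np.ndarray
    blocks: list[Block]
    alpha_idx: dict[tuple[str, str], np.ndarray]
    logk_idx: dict[tuple[str, str], int]
    stay_idx: dict[tuple[str, str], np.ndarray]
    catch_idx: dict[tuple[str, str], int]

    @property
    def dim(self) -> int:
        return self.x0.size


def build_joint_model(data: StudyData, config: StudyConfig) -> JointModel:
    """Lay out the parameter vector and build the per-block log posteriors."""
    config.validate()
    p = config.priors
    n_axes = config.n_pc_axes
    joint_stay = config.stay_mode == "joint"

    names: list[str] = []
    x0_parts: list[float] = []
    alpha_idx, logk_idx, stay_idx, catch_idx = {}, {}, {}, {}

    def _alpha0_init(key: tuple[str, str]) -> float:
        """Moment-based REST point estimate of log density (per km^2)."""
        cbk = data.counts[key]
        if joint_stay:
            ms = st.family_mean(data.stay_family[key[1]], st._init_params(
                data.stay_family[key[1]], data.stay[key]))
        else:
            ms = data.stay_plugin[key]
        total_active = float(cbk.active_s.sum())
        if total_active <= 0:
            return 0.0
        d_hat = max(cbk.n.sum(), 0.5) / (data.focal_area_m2 * total_active) * ms * 1e6
        lo, hi = config.priors.alpha_low, config.priors.alpha_high
        return float(np.clip(np.log(d_hat), lo + 0.1, hi - 0.1))

    ma_keys = sorted(data.counts.keys())
    for key in ma_keys:
        m, a = key
        if key not in data.stay and joint_stay:
            raise ValueError(f"month/age {key} has counts but no staying-time data")
        if not joint_stay and key not in data.stay_plugin:
            raise ValueError(f"month/age {key} has no plug-in staying-time mean")
        base = len(names)
        names += [f"alpha{e}[{m},{a}]" for e in range(n_axes + 1)]
        x0_parts += [_alpha0_init(key)] + [0.0] * n_axes
        alpha_idx[key] = np.arange(base, base + n_axes + 1)
        logk_idx[key] = len(names)
        names.append(f"log_k[{m},{a}]")
        x0_parts.append(0.0)
        if joint_stay:
            fam = st.FAMILIES[data.stay_family[a]]
            base = len(names)
            names += [f"stay_{pn}[{m},{a}]" for pn in fam.param_names]
            x0_parts += list(st._init_params(fam.name, data.stay[key]))
            stay_idx[key] = np.arange(base, base + fam.n_params)

    months_with_harvest = [m for m in data.months if m in data.harvest]
    for m in months_with_harvest:
        if not data.ages_in_month(m):
            raise ValueError(
                f"harvest data in month {m} but no density parameters (no camera data)"
            )
        # moment-based catchability start: catch total / (trap total x density)
        d_rough = sum(np.exp(_alpha0_init((m, a))) for a in data.ages_in_month(m))
        hb = data.harvest[m]
        for trap in TRAP_TYPES:
            catch_idx[(m, trap)] = len(names)
            names.append(f"catch_{trap}[{m}]")
            sel = hb.trap_idx == TRAP_TYPES.index(trap)
            denom = float(hb.n_traps[sel].sum()) * d_rough
            c0 = (hb.n_trapped[sel].sum() + 0.5) / denom if denom > 0 else 0.05
            lo = max(p.catchability_low + 1e-4, 1e-4)
            hi = min(p.catchability_high - 1e-4, 0.5)
            x0_parts.append(float(np.clip(c0, lo, hi)))

    x0 = np.asarray(x0_parts, dtype=float)
    area = data.focal_area_m2
    hc_scale = p.dispersion_half_cauchy_scale
    cells = data.cells
    n_units = len(cells.unit_ids) if cells is not None else 0

    def _mean_stay(x: np.ndarray, key: tuple[str, str]) -> float:
        if not joint_stay:
            return data.stay_plugin[key]
        return st.family_mean(data.stay_family[key[1]], x[stay_idx[key]])

    def _unit_densities(x: np.ndarray, month: str) -> np.ndarray:
        """Forest-weighted unit densities, summed over modelled age classes."""
        total = np.zeros(cells.scores.shape[0])
        for a in data.ages_in_month(month):
            alpha = x[alpha_idx[(month, a)]]
            eta = alpha[0] + cells.scores @ alpha[1:]
            total += np.exp(eta)
        wnum = np.bincount(
            cells.unit_codes, weights=cells.forest_km2 * total, minlength=n_units
        )
        wden = np.bincount(cells.unit_codes, weights=cells.forest_km2, minlength=n_units)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(wden > 0, wnum / np.maximum(wden, 1e-300), 0.0)

    def _harvest_logp(x: np.ndarray, month: str) -> float:
        hb = data.harvest.get(month)
        if hb is None:
            return 0.0
        d_unit = _unit_densities(x, month)
        c = np.array([x[catch_idx[(month, t)]] for t in TRAP_TYPES])
        lam = c[hb.trap_idx] * hb.n_traps * d_unit[hb.unit_idx]
        y = hb.n_trapped
        ll = np.where(
            lam > 0,
            y * np.log(np.maximum(lam, 1e-300)) - lam,
            np.where(y == 0, 0.0, -np.inf),
        )
        return float(np.sum(ll - gammaln(y + 1.0)))

    def _count_stay_logp(x: np.ndarray, key: tuple[str, str]) -> float:
        alpha = x[alpha_idx[key]]
        if np.any(alpha <= p.alpha_low) or np.any(alpha >= p.alpha_high):
            return -np.inf
        log_k = x[logk_idx[key]]
        if abs(log_k) > 30:
            return -np.inf
        k = np.exp(log_k)
        # half-Cauchy(scale) prior on s = 1/sqrt(k), with Jacobian ds/dlogk
        s = np.exp(-0.5 * log_k)
        lp = -np.log1p((s / hc_scale) ** 2) + np.log(0.5 * s)
        cbk = data.counts[key]
        with np.errstate(over="ignore", invalid="ignore"):
            ms = _mean_stay(x, key)
            if not np.isfinite(ms) or ms <= 0:
                return -np.inf
            eta = alpha[0] + cbk.scores @ alpha[1:]
            mu = np.exp(eta) * 1e-6 * area * cbk.active_s / ms
            if np.any(~np.isfinite(mu)) or np.any(mu <= 0):
                return -np.inf
            lp += float(nb_loglik(cbk.n, mu, k).sum())
        if joint_stay:
            sp = x[stay_idx[key]]
            lp += -0.5 * float(np.sum((sp / p.stay_prior_sd) ** 2))
            lp += float(st.family_loglik(data.stay_family[key[1]], data.stay[key], sp).sum())
        return lp if np.isfinite(lp) else -np.inf

    blocks: list[Block] = []
    for key in ma_keys:
        m, a = key

        def logp_alpha(x: np.ndarray, key=key, m=m) -> float:
            lp = _count_stay_logp(x, key)
            if not np.isfinite(lp):
                return -np.inf
            return lp + _harvest_logp(x, m)

        def logp_local(x: np.ndarray, key=key) -> float:
            return _count_stay_logp(x, key)

        blocks.append(Block(f"alpha[{m},{a}]", alpha_idx[key], logp_alpha, init_sd=0.1))
        blocks.append(Block(f"disp[{m},{a}]", np.array([logk_idx[key]]),
                            logp_local, init_sd=0.3))
        if joint_stay:
            blocks.append(Block(f"stay[{m},{a}]", stay_idx[key], logp_local,
                                init_sd=0.05))

    for m in months_with_harvest:
        idx = np.array([catch_idx[(m, t)] for t in TRAP_TYPES])

        def logp_catch(x: np.ndarray, m=m, idx=idx) -> float:
            c = x[idx]
            if np.any(c <= p.catchability_low) or np.any(c >= p.catchability_high):
                return -np.inf
            return _harvest_logp(x, m)

        blocks.append(Block(f"catch[{m}]", idx, logp_catch, init_sd=0.02))

    model = JointModel(
        data=data, config=config, names=names, x0=x0, blocks=blocks,
        alpha_idx=alpha_idx, logk_idx=logk_idx, stay_idx=stay_idx,
        catch_idx=catch_idx,
    )
    model._unit_densities = _unit_densities  # reused for derived summaries
    return model


# ---------------------------------------------------------------------------
# posterior


@dataclass
class PosteriorResult:
    names: list[str]
    draws: np.ndarray  # (chains, kept, dim)
    summary: pd.DataFrame
    seed: int
    accept_rates: pd.DataFrame = field(repr=False, default=None)

    def param_draws(self, name: str) -> np.ndarray:
        return self.draws[:, :, self.names.index(name)]

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        flat = self.param_draws(name).ravel()
        tail = 100.0 * (1.0 - level) / 2.0
        lo, hi = np.percentile(flat, [tail, 100.0 - tail])
        return float(lo), float(hi)

    @property
    def rhat(self) -> pd.Series:
        return self.summary["rhat"]

    def converged(self, threshold: float = 1.1) -> bool:
        return bool((self.summary["rhat"] < threshold).all())


def run_mcmc(model: JointModel, mcmc=None) -> PosteriorResult:
    """Sample the joint posterior with the configured MCMC settings."""
    cfg = mcmc if mcmc is not None else model.config.mcmc
    res = run_blocked_metropolis(
        model.blocks,
        model.x0,
        iterations=cfg.iterations,
        burn_in=cfg.burn_in,
        thin=cfg.thin,
        chains=cfg.chains,
        seed=cfg.seed,
    )
    by_name = {nm: res.draws[:, :, i] for i, nm in enumerate(model.names)}
    summary = summarize_draws(by_name)
    return PosteriorResult(
        names=model.names, draws=res.draws, summary=summary, seed=cfg.seed,
        accept_rates=res.accept_rates,
    )


def _flat(draws: np.ndarray) -> np.ndarray:
    return draws.reshape(-1, draws.shape[-1])


def summarize_unit_densities(model: JointModel, result: PosteriorResult) -> pd.DataFrame:
    """Posterior summaries of forest-weighted unit density (ages summed)."""
    rows = []
    cells = model.data.cells
    for m in model.data.months:
        if not model.data.ages_in_month(m):
            continue
        du = np.stack([model._unit_densities(x, m) for x in _flat(result.draws)])
        for j, u in enumerate(cells.unit_ids):
            q = np.percentile(du[:, j], [2.5, 25, 50, 75, 97.5])
            rows.append(
                {
                    "month": m, "unit_id": u, "mean": du[:, j].mean(),
                    "q2.5": q[0], "q25": q[1], "median": q[2], "q75": q[3],
                    "q97.5": q[4],
                }
            )
    return pd.DataFrame(rows)


def summarize_area_density(model: JointModel, result: PosteriorResult) -> pd.DataFrame:
    """Study-area mean density per month and age (forest-weighted over cells)."""
    cells = model.data.cells
    w = cells.forest_km2 / cells.forest_km2.sum()
    rows = []
    flat = _flat(result.draws)
    for (m, a), idx in model.alpha_idx.items():
        alphas = flat[:, idx]
        eta = alphas[:, [0]] + alphas[:, 1:] @ cells.scores.T
        d = np.exp(eta) @ w
        q = np.percentile(d, [2.5, 25, 50, 75, 97.5])
        rows.append(
            {
                "month": m, "age_class": a, "mean": d.mean(), "q2.5": q[0],
                "q25": q[1], "median": q[2], "q75": q[3], "q97.5": q[4],
            }
        )
    return pd.DataFrame(rows).sort_values(["month", "age_class"]).reset_index(drop=True)


@dataclass
class FitResult:
    posterior: PosteriorResult
    model: JointModel
    basis: PcaBasis
    activity: dict[tuple[str, str], ActivityEstimate]
    stay_sweeps: dict[str, list[st.StayingTimeModel]]
    area_density: pd.DataFrame
    unit_density: pd.DataFrame


def run_fit(
    config: StudyConfig,
    tables: dict[str, pd.DataFrame],
    *,
    mcmc=None,
    stay_sweep_kwargs: dict | None = None,
) -> FitResult:
    """End-to-end fit from validated tables (keys: detections, deployments,
    sites, cells, harvest, units)."""
    data, basis, extras = build_study_data(
        tables["detections"], tables["deployments"], tables["sites"],
        tables["cells"], tables["harvest"], tables["units"], config,
        stay_sweep_kwargs=stay_sweep_kwargs,
    )
    model = build_joint_model(data, config)
    post = run_mcmc(model, mcmc)
    return FitResult(
        posterior=post,
        model=model,
        basis=basis,
        activity=extras["activity"],
        stay_sweeps=extras["stay_sweeps"],
        area_density=summarize_area_density(model, post),
        unit_density=summarize_unit_densities(model, post),
    )
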
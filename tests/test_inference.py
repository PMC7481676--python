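"""Joint-model assembly, log-posterior oracles and effort accounting."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from boarest.config import McmcConfig
from boarest.inference import (
    build_joint_model,
    build_study_data,
    monthly_deployment_seconds,
    run_mcmc,
)
from boarest.rest import nb_loglik
from boarest.simulate import study_config_for
from boarest.staying_time import family_loglik, family_mean


@pytest.fixture(scope="module")
def built(small_study):
    sim = small_study
    cfg = study_config_for(sim.truth, stay_families=["lognormal"])
    data, basis, extras = build_study_data(
        sim.detections, sim.deployments, sim.landscape.sites,
        sim.landscape.cells, sim.harvest, sim.landscape.units, cfg,
    )
    model = build_joint_model(data, cfg)
    return sim, cfg, data, model


def test_monthly_deployment_accounts_partial_months():
    dep = pd.DataFrame(
        {
            "camera_id": ["c1", "c2"],
            "start": pd.to_datetime(["2018-06-16", "2018-06-01"]),
            "end": pd.to_datetime(["2018-07-01", "2018-08-01"]),
        }
    )
    eff = monthly_deployment_seconds(dep, ["2018-06", "2018-07"])
    assert eff.loc["c1", "2018-06"] == 15 * 86400.0
    assert eff.loc["c1", "2018-07"] == 0.0
    assert eff.loc["c2", "2018-06"] == 30 * 86400.0
    assert eff.loc["c2", "2018-07"] == 31 * 86400.0


def test_parameter_layout_covers_all_data(built):
    sim, cfg, data, model = built
    months = set(sim.truth.months)
    assert {m for (m, a) in data.counts} == months
    for m in months:
        assert ("adult" in data.ages_in_month(m))
        assert (m, "box") in model.catch_idx and (m, "snare") in model.catch_idx
    # juveniles only in the configured months
    juv = {m for (m, a) in data.counts if a == "juvenile"}
    assert juv == set(sim.truth.juvenile_months)


def test_log_posterior_matches_hand_summed_components(built):
    """Component-wise oracle at a fixed parameter point."""
    sim, cfg, data, model = built
    x = model.x0.copy()
    rng = np.random.default_rng(0)
    x += 0.05 * rng.standard_normal(x.size)
    for i in model.catch_idx.values():  # keep catchabilities interior to (0, 1)
        x[i] = abs(x[i]) + 1e-3
    m, a = sorted(data.counts)[0]
    blk = next(b for b in model.blocks if b.name == f"alpha[{m},{a}]")

    alpha = x[model.alpha_idx[(m, a)]]
    log_k = x[model.logk_idx[(m, a)]]
    sp = x[model.stay_idx[(m, a)]]
    cb = data.counts[(m, a)]
    ms = family_mean("lognormal", sp)
    mu = np.exp(alpha[0] + cb.scores @ alpha[1:]) * 1e-6 * data.focal_area_m2 \
        * cb.active_s / ms
    expected = float(nb_loglik(cb.n, mu, np.exp(log_k)).sum())
    expected += float(family_loglik("lognormal", data.stay[(m, a)], sp).sum())
    # priors: N(0, sd) on stay params, half-Cauchy on 1/sqrt(k)
    expected += -0.5 * float(np.sum((sp / cfg.priors.stay_prior_sd) ** 2))
    s = np.exp(-0.5 * log_k)
    expected += -np.log1p((s / cfg.priors.dispersion_half_cauchy_scale) ** 2) \
        + np.log(0.5 * s)
    # harvest term for this month, hand-computed
    hb = data.harvest[m]
    cells = data.cells
    total = np.zeros(cells.scores.shape[0])
    for age in data.ages_in_month(m):
        al = x[model.alpha_idx[(m, age)]]
        total += np.exp(al[0] + cells.scores @ al[1:])
    wnum = np.bincount(cells.unit_codes, weights=cells.forest_km2 * total)
    wden = np.bincount(cells.unit_codes, weights=cells.forest_km2)
    d_unit = wnum / wden
    c = np.array([x[model.catch_idx[(m, t)]] for t in ("box", "snare")])
    lam = c[hb.trap_idx] * hb.n_traps * d_unit[hb.unit_idx]
    y = hb.n_trapped
    expected += float(np.sum(y * np.log(lam) - lam - gammaln(y + 1)))

    assert blk.logp(x) == pytest.approx(expected, rel=1e-10)


def test_alpha_outside_prior_support_is_rejected(built):
    sim, cfg, data, model = built
    key = sorted(data.counts)[0]
    blk = next(b for b in model.blocks if b.name == f"alpha[{key[0]},{key[1]}]")
    x = model.x0.copy()
    x[model.alpha_idx[key][0]] = 3.5
    assert blk.logp(x) == -np.inf


def test_catchability_outside_unit_interval_rejected(built):
    sim, cfg, data, model = built
    m = sim.truth.months[0]
    blk = next(b for b in model.blocks if b.name == f"catch[{m}]")
    x = model.x0.copy()
    x[model.catch_idx[(m, "box")]] = 1.2
    assert blk.logp(x) == -np.inf


def test_empty_harvest_reduces_to_rest_only(small_study):
    """With no harvest rows the model has no catchability parameters and the
    month/age blocks carry only count + staying-time terms."""
    sim = small_study
    cfg = study_config_for(sim.truth, stay_families=["lognormal"])
    empty = sim.harvest.iloc[0:0]
    data, _, _ = build_study_data(
        sim.detections, sim.deployments, sim.landscape.sites,
        sim.landscape.cells, empty, sim.landscape.units, cfg,
    )
    model = build_joint_model(data, cfg)
    assert model.catch_idx == {}
    assert not any(b.name.startswith("catch") for b in model.blocks)

    # and the block log-density equals the count+stay component alone
    full_data, _, _ = build_study_data(
        sim.detections, sim.deployments, sim.landscape.sites,
        sim.landscape.cells, sim.harvest, sim.landscape.units, cfg,
    )
    full_model = build_joint_model(full_data, cfg)
    key = sorted(data.counts)[0]
    x_small = model.x0 + 0.03
    blk = next(b for b in model.blocks if b.name == f"alpha[{key[0]},{key[1]}]")
    lp_rest_only = blk.logp(x_small)
    assert np.isfinite(lp_rest_only)


def test_run_mcmc_reproducible_and_counts_draws(built):
    sim, cfg, data, model = built
    mc = McmcConfig(iterations=300, burn_in=100, thin=4, chains=2, seed=5)
    r1 = run_mcmc(model, mc)
    r2 = run_mcmc(model, mc)
    assert np.array_equal(r1.draws, r2.draws)
    assert r1.draws.shape == (2, 50, model.dim)


def test_default_mcmc_settings_keep_2000_draws_per_chain():
    mc = McmcConfig()
    assert (mc.iterations - mc.burn_in) // mc.thin == 2000
    assert mc.chains == 3
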
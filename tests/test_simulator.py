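"""Generative simulator: validity of outputs and moment oracles."""

import numpy as np
import pandas as pd
import pytest

from boarest import io as bio
from boarest.landscape import LANDSCAPE_CLASSES, fit_pca
from boarest.rest import expected_count, focal_area_from_side
from boarest.simulate import (
    default_truth,
    simulate_camera_data,
    simulate_harvest,
    simulate_landscape,
    simulate_study,
)


class TestLandscape:
    def test_compositions_valid_and_forest_consistent(self):
        ls = simulate_landscape(60, 120, 6, seed=1)
        for df in (ls.sites, ls.cells):
            x = df[LANDSCAPE_CLASSES].to_numpy()
            assert np.all(x >= 0) and np.all(x <= 100)
            assert np.all(x.sum(axis=1) <= 100.0 + 1e-9)
        forest = ls.cells[["broadleaf", "conifer", "bamboo"]].sum(axis=1) / 100.0
        assert np.allclose(ls.units["forest_area_km2"], forest)
        assert ls.units["unit_id"].nunique() == 6

    def test_fixed_seed_reproducible(self):
        a = simulate_landscape(20, 40, 4, seed=9)
        b = simulate_landscape(20, 40, 4, seed=9)
        pd.testing.assert_frame_equal(a.sites, b.sites)
        pd.testing.assert_frame_equal(a.units, b.units)

    def test_more_units_than_cells_rejected(self):
        with pytest.raises(ValueError):
            simulate_landscape(10, 5, 6, seed=0)

    def test_four_axes_explain_most_variance(self):
        ls = simulate_landscape(500, 10, 2, seed=3)
        basis = fit_pca(ls.sites)
        assert basis.explained_ratio[:4].sum() > 0.70


class TestCameraData:
    def test_count_moments_match_nb_oracle(self):
        """Empirical mean ~ mu and variance ~ mu + mu^2/k over many replicate
        cameras with identical scores."""
        truth = default_truth(["2018-06"], juvenile_months=[])
        scores = pd.DataFrame(
            np.zeros((5000, 4)), columns=[f"PC{j+1}" for j in range(4)],
            index=[f"cam{i}" for i in range(5000)],
        )
        det = simulate_camera_data(truth, scores, "2018-06", seed=4)
        counts = det.groupby("camera_id").size().reindex(scores.index, fill_value=0)
        area = focal_area_from_side(1.9).area_m2
        active = 30 * 86400.0 * truth.activity_proportion("2018-06", "adult")
        mu = expected_count(
            truth.alpha[("2018-06", "adult")], np.zeros(4), area,
            truth.mean_stay("2018-06", "adult"), active,
        )
        k = truth.nb_k[("2018-06", "adult")]
        assert counts.mean() == pytest.approx(mu, rel=0.02)
        assert counts.var(ddof=1) == pytest.approx(mu + mu**2 / k, rel=0.10)

    def test_unknown_month_rejected(self):
        truth = default_truth(["2018-06"], juvenile_months=[])
        scores = pd.DataFrame(np.zeros((3, 4)), columns=[f"PC{j+1}" for j in range(4)])
        with pytest.raises(ValueError, match="missing"):
            simulate_camera_data(truth, scores, "2019-01", seed=0)

    def test_staying_times_positive_and_timestamps_in_month(self, small_study):
        det = small_study.detections
        assert (det["staying_time_s"] > 0).all()
        months = pd.to_datetime(det["timestamp"]).dt.strftime("%Y-%m")
        assert set(months) <= set(small_study.truth.months)


class TestHarvest:
    def test_zero_traps_zero_catch_and_poisson_mean(self):
        truth = default_truth(["2018-06"], juvenile_months=[])
        dens = pd.Series({f"u{i}": 8.0 for i in range(20_000)})
        trap_table = pd.DataFrame(
            [{"unit_id": u, "trap_type": t, "n_traps": 0 if i % 7 == 0 else 10}
             for i, u in enumerate(dens.index) for t in ("box", "snare")]
        )
        h = simulate_harvest(truth, dens, "2018-06", seed=5, trap_table=trap_table)
        no_traps = h[h["n_traps"] == 0]
        assert (no_traps["n_trapped"] == 0).all()
        box = h[(h["trap_type"] == "box") & (h["n_traps"] == 10)]
        lam = 0.02 * 10 * 8.0
        assert box["n_trapped"].mean() == pytest.approx(lam, rel=0.02)

    def test_doubling_catchability_doubles_mean_catch(self):
        t1 = default_truth(["2018-06"], juvenile_months=[])
        t2 = default_truth(["2018-06"], juvenile_months=[])
        t2.catchability[("2018-06", "box")] *= 2
        dens = pd.Series({f"u{i}": 8.0 for i in range(3000)})
        tt = pd.DataFrame([{"unit_id": u, "trap_type": "box", "n_traps": 10}
                           for u in dens.index])
        h1 = simulate_harvest(t1, dens, "2018-06", seed=6, trap_table=tt)
        h2 = simulate_harvest(t2, dens, "2018-06", seed=6, trap_table=tt)
        b1 = h1[h1["trap_type"] == "box"]["n_trapped"].mean()
        b2 = h2[h2["trap_type"] == "box"]["n_trapped"].mean()
        assert b2 / b1 == pytest.approx(2.0, rel=0.05)


def test_simulator_outputs_pass_io_validators(tmp_path, small_study):
    sim = small_study
    bio.write_detections(sim.detections, tmp_path / "d.csv")
    bio.read_detections(tmp_path / "d.csv")
    bio.write_harvest(sim.harvest, tmp_path / "h.csv")
    bio.read_harvest(tmp_path / "h.csv")
    bio.write_landscape(sim.landscape.sites, tmp_path / "s.csv")
    bio.read_landscape(tmp_path / "s.csv", "site_id")
    bio.write_landscape(sim.landscape.cells, tmp_path / "c.csv")
    bio.read_landscape(tmp_path / "c.csv", "cell_id")
    bio.write_units(sim.landscape.units, tmp_path / "u.csv")
    bio.read_units(tmp_path / "u.csv")


def test_study_seed_determinism():
    t = default_truth(["2018-06", "2018-07"], juvenile_months=["2018-06"])
    ls = simulate_landscape(15, 30, 3, seed=2)
    a = simulate_study(t, ls, seed=8)
    b = simulate_study(t, ls, seed=8)
    pd.testing.assert_frame_equal(a.detections, b.detections)
    pd.testing.assert_frame_equal(a.harvest, b.harvest)
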
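"""Sampler correctness (conjugate oracle, determinism), Rhat and WAIC."""

import numpy as np
import pytest

from boarest.mcmc import Block, run_blocked_metropolis, split_rhat, summarize_draws, waic


def _poisson_lograte_model(y):
    """Single log-rate theta with flat prior on theta."""
    s, n = y.sum(), y.size

    def logp(x):
        theta = x[0]
        if abs(theta) > 30:
            return -np.inf
        return s * theta - n * np.exp(theta)

    return [Block("theta", np.array([0]), logp, init_sd=0.2)]


class TestSampler:
    def test_conjugate_poisson_posterior_mean(self, rng):
        """Flat prior on log-rate => rate | y ~ Gamma(sum y, n); the MCMC
        posterior mean of the rate must match sum(y)/n within MC error."""
        y = rng.poisson(4.0, size=50)
        blocks = _poisson_lograte_model(y)
        res = run_blocked_metropolis(
            blocks, np.array([0.0]), iterations=12000, burn_in=2000, thin=2,
            chains=3, seed=7,
        )
        lam = np.exp(res.draws[:, :, 0])
        analytic_mean = y.sum() / y.size
        analytic_sd = np.sqrt(y.sum()) / y.size
        mc_se = lam.std() / np.sqrt(lam.size / 20)  # conservative ESS guess
        assert abs(lam.mean() - analytic_mean) < max(3 * mc_se, 0.05 * analytic_sd * 3)
        assert lam.std() == pytest.approx(analytic_sd, rel=0.15)

    def test_same_seed_identical_draws(self, rng):
        y = rng.poisson(2.0, size=20)
        kw = dict(iterations=400, burn_in=100, thin=2, chains=2, seed=123)
        d1 = run_blocked_metropolis(_poisson_lograte_model(y), np.zeros(1), **kw).draws
        d2 = run_blocked_metropolis(_poisson_lograte_model(y), np.zeros(1), **kw).draws
        assert np.array_equal(d1, d2)

    def test_kept_draw_count_follows_settings(self, rng):
        y = rng.poisson(2.0, size=20)
        res = run_blocked_metropolis(
            _poisson_lograte_model(y), np.zeros(1),
            iterations=50_0, burn_in=10_0, thin=2, chains=3, seed=1,
        )
        assert res.draws.shape == (3, (500 - 100) // 2, 1)


class TestRhat:
    def test_converged_white_noise_near_one(self, rng):
        draws = rng.normal(0, 1, size=(3, 1000))
        assert split_rhat(draws) < 1.05

    def test_separated_chains_flagged(self, rng):
        draws = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert split_rhat(draws) > 3.0

    def test_matches_textbook_between_within_formula(self, rng):
        """Independent oracle: split into halves, compute B and W longhand."""
        draws = rng.normal(0, 1, size=(2, 100)).cumsum(axis=1) * 0.05 + rng.normal(
            0, 1, size=(2, 100)
        )
        seqs = np.array([draws[0, :50], draws[0, 50:], draws[1, :50], draws[1, 50:]])
        m, L = 4, 50
        means = seqs.mean(axis=1)
        w = np.mean([s.var(ddof=1) for s in seqs])
        b = L / (m - 1) * np.sum((means - means.mean()) ** 2)
        expected = np.sqrt(((L - 1) / L * w + b / L) / w)
        assert split_rhat(draws) == pytest.approx(expected, rel=1e-12)

    def test_matches_arviz_split_rhat(self, rng):
        az = pytest.importorskip("arviz")
        draws = rng.normal(0, 1, size=(4, 250)) + rng.normal(0, 0.3, size=(4, 1))
        ours = split_rhat(draws)
        theirs = az.rhat(az.convert_to_dataset(draws[:, :, None]),
                         method="split")["x"].values.item()
        assert ours == pytest.approx(theirs, rel=1e-6)

    def test_requires_multiple_chains(self, rng):
        with pytest.raises(ValueError):
            split_rhat(rng.normal(size=(1, 100)))


class TestWaic:
    def test_matches_arviz_deviance_scale(self, rng):
        az = pytest.importorskip("arviz")
        ll = rng.normal(-1.2, 0.3, size=(400, 25))
        ours = waic(ll)
        idata = az.from_dict(
            posterior={"dummy": rng.normal(size=(1, 400))},
            log_likelihood={"y": ll[None, :, :]},
        )
        theirs = az.waic(idata, scale="deviance")
        # arviz computes the pointwise variance with ddof=0; we use the
        # textbook sample variance (ddof=1) -> agree to O(1/n_draws)
        assert ours.waic == pytest.approx(float(theirs.elpd_waic), rel=1e-3)
        assert ours.p_waic == pytest.approx(float(theirs.p_waic), rel=1e-2)

    def test_identical_draws_have_zero_penalty(self):
        ll = np.tile(np.array([-1.0, -2.0, -0.5]), (10, 1))
        res = waic(ll)
        assert res.p_waic == 0.0
        assert res.waic == pytest.approx(-2 * ll[0].sum())


def test_summarize_draws_quantiles_and_rhat(rng):
    draws = {"a": rng.normal(2.0, 1.0, size=(3, 400))}
    s = summarize_draws(draws)
    assert s.loc["a", "mean"] == pytest.approx(2.0, abs=0.1)
    assert s.loc["a", "q2.5"] < s.loc["a", "q25"] < s.loc["a", "median"]
    assert s.loc["a", "rhat"] < 1.05
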
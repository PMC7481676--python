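"""REST geometry, density equation, and negative-binomial likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy import integrate, stats

from boarest.rest import (
    expected_count,
    focal_area_from_side,
    nb_loglik,
    rest_density_point,
)


def _shoelace(vertices):
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@pytest.mark.parametrize("side, expected", [(2.0, np.sqrt(3.0)), (1.9, 1.5632)])
def test_focal_area_matches_shoelace_oracle(side, expected):
    fa = focal_area_from_side(side)
    assert fa.area_m2 == pytest.approx(expected, abs=5e-5)
    verts = side * np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
    assert fa.area_m2 == pytest.approx(_shoelace(verts), abs=1e-12)


def test_focal_area_rejects_nonpositive_side():
    for side in (0.0, -1.9):
        with pytest.raises(ValueError):
            focal_area_from_side(side)


def test_rest_density_hand_evaluated_example():
    """20 passages, 1.5632 m^2, 8 s stay, 1e6 s active -> 102.35 km^-2."""
    d = rest_density_point(20, 1.5632, 8.0, 1_000_000.0)
    assert d == pytest.approx(20 * 8 / (1.5632 * 1e6) * 1e6, rel=1e-12)
    assert d == pytest.approx(102.35, abs=0.01)
    assert rest_density_point(0, 1.5632, 8.0, 1e6) == 0.0


@given(
    n=st_.integers(1, 500),
    stay=st_.floats(0.5, 60.0),
    scale=st_.floats(0.1, 10.0),
)
@settings(max_examples=50, deadline=None)
def test_rest_density_scaling_laws(n, stay, scale):
    """Linear in count and staying time; inverse-linear in area and effort."""
    base = rest_density_point(n, 1.5632, stay, 2.0e6)
    assert rest_density_point(n * 2, 1.5632, stay, 2.0e6) == pytest.approx(2 * base)
    assert rest_density_point(n, 1.5632, stay * scale, 2.0e6) == pytest.approx(scale * base)
    assert rest_density_point(n, 1.5632 * scale, stay, 2.0e6) == pytest.approx(base / scale)
    assert rest_density_point(n, 1.5632, stay, 2.0e6 * scale) == pytest.approx(base / scale)


def test_expected_count_baseline_and_log_link():
    area, stay, active = 1.5632, 8.0, 1.0e6
    base = expected_count(np.zeros(5), np.zeros(4), area, stay, active)
    assert base == pytest.approx(1e-6 * area * active / stay, rel=1e-12)
    doubled = expected_count(
        np.array([0.0, np.log(2.0), 0.0, 0.0, 0.0]),
        np.array([1.0, 0.0, 0.0, 0.0]), area, stay, active,
    )
    assert doubled == pytest.approx(2.0 * base, rel=1e-12)


@given(
    alpha=st_.lists(st_.floats(-2, 2), min_size=5, max_size=5),
    scores=st_.lists(st_.floats(-2, 2), min_size=4, max_size=4),
)
@settings(max_examples=50, deadline=None)
def test_expected_count_round_trips_density(alpha, scores):
    """rest_density_point(expected_count(...)) recovers exp(linear predictor)."""
    alpha, scores = np.array(alpha), np.array(scores)
    area, stay, active = 1.5632, 7.7, 2.6e6
    mu = expected_count(alpha, scores, area, stay, active)
    d = rest_density_point(mu, area, stay, active)
    assert d == pytest.approx(float(np.exp(alpha[0] + alpha[1:] @ scores)), rel=1e-10)


class TestNbLoglik:
    def test_poisson_limit(self):
        n, mu = 2, 3.0
        pois = stats.poisson.logpmf(n, mu)
        assert abs(nb_loglik(n, mu, 1e8) - pois) < 1e-4

    def test_normalizes_to_one(self):
        ns = np.arange(0, 400)
        total = np.exp(nb_loglik(ns, 2.5, 1.3)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_matches_gamma_poisson_quadrature_oracle(self):
        """NB pmf as the integral of Poisson(n | lam) over lam ~ Gamma(k, k/mu)."""
        n, mu, k = 4, 2.5, 1.3

        def integrand(lam):
            return stats.poisson.pmf(n, lam) * stats.gamma.pdf(lam, a=k, scale=mu / k)

        val, _ = integrate.quad(integrand, 0, np.inf)
        assert np.exp(nb_loglik(n, mu, k)) == pytest.approx(val, abs=1e-8)

    def test_matches_scipy_parameterization(self):
        n, mu, k = np.arange(6), 3.7, 2.2
        ours = nb_loglik(n, mu, k)
        theirs = stats.nbinom.logpmf(n, k, k / (k + mu))
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_rejects_invalid_parameters(self):
        with pytest.raises(ValueError):
            nb_loglik(2, -1.0, 1.0)
        with pytest.raises(ValueError):
            nb_loglik(2, 1.0, 0.0)
        with pytest.raises(ValueError):
            nb_loglik(-1, 1.0, 1.0)
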
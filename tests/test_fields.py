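import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import kv

from stdelta.fields import (
    FieldParams,
    FieldRealization,
    field_log_density,
    knot_correlation,
    matern_correlation,
    simulate_fields,
)
from stdelta.geo import build_mesh

from conftest import km_table as _table


def _mesh(xy, n_knots, seed=0):
    return build_mesh(_table(xy), n_knots, buffer_km=50, seed=seed)


class TestMaternCorrelation:
    def test_zero_distance_is_one(self):
        c = matern_correlation(np.zeros((3, 3)), range_km=50.0)
        assert np.allclose(np.diag(c), 1.0, atol=1e-6)

    def test_correlation_at_range_is_point_one(self):
        d = np.array([[0.0, 80.0], [80.0, 0.0]])
        c = matern_correlation(d, range_km=80.0)
        assert c[0, 1] == pytest.approx(0.10, abs=1e-6)

    def test_matches_independent_bessel_evaluation(self, rng):
        # independent oracle: solve kappa from (kappa*range) K1(kappa*range) = 0.1
        # by bisection, then evaluate (kappa d) K1(kappa d) entrywise
        range_km = 120.0
        pts = rng.uniform(0, 300, size=(5, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        d = 0.5 * (d + d.T)
        kappa = brentq(lambda k: k * range_km * kv(1, k * range_km) - 0.1,
                       1e-6, 1.0) if True else None
        expect = np.ones_like(d)
        off = d > 0
        expect[off] = kappa * d[off] * kv(1, kappa * d[off])
        got = matern_correlation(d, range_km)
        assert np.allclose(got[off], expect[off], atol=1e-10)

    def test_rejects_asymmetric(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            matern_correlation(d, 50.0)


class TestSimulateFields:
    def test_zero_sd_gives_zero_fields(self, rng):
        mesh = _mesh(rng.uniform([0, 6000], [300, 6200], (20, 2)), 5)
        real = simulate_fields(mesh, FieldParams(range_km=100.0), n_years=3, seed=1)
        assert not real.omega1.any() and not real.eps1.any()
        assert real.eps1.shape == (5, 3)

    def test_marginal_variance_monte_carlo(self, rng):
        # sample variance of eps across many independent years approaches sd^2
        mesh = _mesh(rng.uniform([0, 6000], [300, 6200], (20, 2)), 4)
        params = FieldParams(sd_eps1=0.7, range_km=100.0)
        real = simulate_fields(mesh, params, n_years=5000, seed=7)
        v = real.eps1[0].var()
        assert v == pytest.approx(0.49, rel=0.05)

    def test_pairwise_correlation_monte_carlo(self, rng):
        mesh = _mesh(rng.uniform([0, 6000], [300, 6200], (30, 2)), 6)
        params = FieldParams(sd_eps1=1.0, range_km=150.0)
        real = simulate_fields(mesh, params, n_years=5000, seed=11)
        corr_target = knot_correlation(mesh.knots, 150.0)
        # closest pair of knots: highest correlation, clearest signal
        d = np.sqrt(((mesh.knots[:, None] - mesh.knots[None, :]) ** 2).sum(-1))
        d[np.diag_indices_from(d)] = np.inf
        i, j = np.unravel_index(np.argmin(d), d.shape)
        emp = np.corrcoef(real.eps1[i], real.eps1[j])[0, 1]
        assert emp == pytest.approx(corr_target[i, j], abs=0.03)

    def test_reproducible_under_seed(self, rng):
        mesh = _mesh(rng.uniform([0, 6000], [300, 6200], (20, 2)), 5)
        params = FieldParams(sd_omega1=0.5, sd_eps1=0.5, range_km=100.0)
        a = simulate_fields(mesh, params, n_years=4, seed=3)
        b = simulate_fields(mesh, params, n_years=4, seed=3)
        assert np.array_equal(a.omega1, b.omega1)
        assert np.array_equal(a.eps1, b.eps1)


class TestFieldLogDensity:
    def _one_knot_mesh(self):
        return _mesh([[0, 6000], [500, 6400]], 1)

    def test_standard_normal_at_zero(self):
        mesh = self._one_knot_mesh()
        real = FieldRealization.zeros(1, 1)
        real.omega1 = np.array([0.0])
        lp = field_log_density(real, FieldParams(sd_omega1=1.0, range_km=100.0), mesh)
        assert lp == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-6)

    def test_univariate_normal_formula(self):
        # N(0, 2^2) at x=2: -log(2 sqrt(2 pi)) - 0.5
        mesh = self._one_knot_mesh()
        real = FieldRealization.zeros(1, 1)
        real.omega1 = np.array([2.0])
        lp = field_log_density(real, FieldParams(sd_omega1=2.0, range_km=100.0), mesh)
        assert lp == pytest.approx(-0.5 * np.log(2 * np.pi) - np.log(2.0) - 0.5,
                                   abs=1e-6)

    def test_epsilon_years_are_independent_blocks(self, rng):
        mesh = _mesh(rng.uniform([0, 6000], [300, 6200], (20, 2)), 4)
        params = FieldParams(sd_eps1=0.8, range_km=120.0)
        real = simulate_fields(mesh, params, n_years=3, seed=5)
        total = field_log_density(real, params, mesh)
        per_year = 0.0
        for t in range(3):
            one = FieldRealization.zeros(4, 1)
            one.eps1 = real.eps1[:, [t]]
            per_year += field_log_density(one, params, mesh)
        assert total == pytest.approx(per_year, rel=1e-12)

    def test_zero_sd_with_nonzero_values_rejected(self):
        mesh = self._one_knot_mesh()
        real = FieldRealization.zeros(1, 1)
        real.omega2 = np.array([0.5])
        with pytest.raises(ValueError, match="omega2"):
            field_log_density(real, FieldParams(sd_omega1=1.0, range_km=100.0), mesh)

    def test_mean_log_density_matches_entropy(self, rng):
        # E[log p(X)] = -H = -(n/2)(1 + log 2pi) - (1/2) log det(Sigma)
        mesh = _mesh(rng.uniform([0, 6000], [300, 6200], (25, 2)), 5)
        params = FieldParams(sd_omega1=0.6, range_km=100.0)
        corr = knot_correlation(mesh.knots, 100.0)
        _, logdet = np.linalg.slogdet(0.36 * corr)
        expect = -(5 / 2) * (1 + np.log(2 * np.pi)) - 0.5 * logdet
        gen = np.random.default_rng(17)
        draws = []
        for _ in range(3000):
            real = simulate_fields(mesh, params, n_years=1, seed=gen)
            draws.append(field_log_density(real, params, mesh))
        assert np.mean(draws) == pytest.approx(expect, rel=0.02)
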
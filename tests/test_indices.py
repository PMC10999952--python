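import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from conftest import toy_stations

from stdelta.fields import FieldRealization
from stdelta.geo import build_mesh
from stdelta.indices import (
    DensitySurface,
    abundance_index,
    bias_correct_indices,
    center_of_gravity,
    effective_area_occupied,
    indices_from_surface,
    predict_density,
)
from stdelta.model import LikelihoodContext, ModelConfig, fit

from test_model import _plain_fit


def _surface(d, areas=None, xy=None, years=None):
    d = np.atleast_2d(np.asarray(d, dtype=float))
    n_cells, n_years = d.shape
    return DensitySurface(
        cell_xy=np.asarray(xy, dtype=float) if xy is not None else
        np.column_stack([np.arange(n_cells, dtype=float),
                         np.zeros(n_cells)]),
        cell_area=np.asarray(areas, dtype=float) if areas is not None else
        np.ones(n_cells),
        years=np.asarray(years) if years is not None else 2000 + np.arange(n_years),
        d=d,
    )


class TestSurfaceOracles:
    def test_uniform_surface_index_is_total_biomass(self):
        s = _surface(np.ones((100, 1)), areas=np.full(100, 10.0))
        assert abundance_index(s)[0] == pytest.approx(1000.0)

    def test_index_is_linear_in_density(self, rng):
        d = rng.gamma(1, 1, size=(50, 3))
        areas = rng.uniform(5, 15, 50)
        s1 = _surface(d, areas=areas)
        s2 = _surface(2 * d, areas=areas)
        assert np.allclose(abundance_index(s2), 2 * abundance_index(s1))

    def test_index_matches_brute_force_sum(self, rng):
        d = rng.gamma(1, 1, size=(40, 4))
        areas = rng.uniform(1, 5, 40)
        s = _surface(d, areas=areas)
        brute = np.array([sum(areas[i] * d[i, t] for i in range(40))
                          for t in range(4)])
        assert np.allclose(abundance_index(s), brute, rtol=1e-14)

    def test_cog_symmetric_uniform_grid(self):
        xs, ys = np.meshgrid(np.linspace(-50, 50, 11), np.linspace(100, 200, 11))
        xy = np.column_stack([xs.ravel(), ys.ravel()])
        s = _surface(np.ones((121, 1)), xy=xy)
        northing, easting = center_of_gravity(s)
        assert easting[0] == pytest.approx(0.0, abs=1e-9)
        assert northing[0] == pytest.approx(150.0, abs=1e-9)

    def test_cog_weighted_mean_by_hand(self):
        xy = np.array([[0.0, 0.0], [0.0, 100.0]])
        s = _surface(np.array([[1.0], [3.0]]), xy=xy)
        northing, _ = center_of_gravity(s)
        assert northing[0] == pytest.approx(75.0)

    def test_cog_matches_brute_force(self, rng):
        d = rng.gamma(1, 1, size=(30, 2))
        xy = rng.uniform(0, 500, size=(30, 2))
        areas = rng.uniform(1, 4, 30)
        s = _surface(d, areas=areas, xy=xy)
        northing, easting = center_of_gravity(s)
        for t in range(2):
            w = areas * d[:, t]
            assert northing[t] == pytest.approx(np.sum(xy[:, 1] * w) / w.sum())
            assert easting[t] == pytest.approx(np.sum(xy[:, 0] * w) / w.sum())

    def test_cog_undefined_for_empty_year(self):
        s = _surface(np.zeros((10, 1)))
        northing, easting = center_of_gravity(s)
        assert np.isnan(northing[0]) and np.isnan(easting[0])

    def test_eao_uniform_density_occupies_total_area(self):
        s = _surface(np.full((60, 1), 2.5), areas=np.full(60, 7.0))
        assert effective_area_occupied(s)[0] == pytest.approx(420.0)

    def test_eao_point_concentration_occupies_one_cell(self):
        d = np.zeros((20, 1))
        d[4, 0] = 9.0
        s = _surface(d, areas=np.full(20, 100.0))
        assert effective_area_occupied(s)[0] == pytest.approx(100.0)

    def test_eao_bounded_by_total_area(self, rng):
        # Cauchy-Schwarz: (sum a d)^2 <= (sum a)(sum a d^2)
        for _ in range(20):
            d = rng.gamma(0.5, 2, size=(30, 1))
            areas = rng.uniform(1, 10, 30)
            s = _surface(d, areas=areas)
            assert effective_area_occupied(s)[0] <= areas.sum() * (1 + 1e-12)

    def test_northward_shift_detected_by_cog(self, rng):
        # density ridge moving north year over year, noisy surfaces
        ys = np.linspace(0, 400, 40)
        xy = np.column_stack([np.zeros(40), ys])
        rhos = []
        for _ in range(20):
            centers = np.linspace(100, 300, 6)
            d = np.exp(-((ys[:, None] - centers[None, :]) / 80) ** 2)
            d *= rng.lognormal(0, 0.3, size=d.shape)
            s = _surface(d, xy=xy, years=2000 + np.arange(6))
            northing, _ = center_of_gravity(s)
            rhos.append(spearmanr(np.arange(6), northing).statistic)
        assert np.mean(rhos) > 0.8


class TestPredictDensity:
    def test_all_parameters_zero_gives_unit_density(self):
        st = toy_stations(30, n_years=2)
        mesh = build_mesh(st, 4, buffer_km=50, seed=0)
        f = _plain_fit(st, mesh, [0.0, 0.0], [0.0, 0.0])
        surf = predict_density(f)
        assert np.allclose(surf.d, 1.0)

    def test_log_two_predictor_doubles_density(self):
        st = toy_stations(30)
        mesh = build_mesh(st, 4, buffer_km=50, seed=0)
        f = _plain_fit(st, mesh, [np.log(2.0)], [0.0])
        surf = predict_density(f)
        assert np.allclose(surf.d, 2.0)

    def test_two_knot_field_chain_by_hand(self):
        st = toy_stations(30)
        mesh = build_mesh(st, 2, buffer_km=50, seed=0)
        re = FieldRealization.zeros(2, 1)
        re.omega1 = np.array([0.5, -0.5])
        f = _plain_fit(st, mesh, [0.2], [0.3], re=re)
        surf = predict_density(f)
        knot_id = mesh.grid_cells["knot_id"].to_numpy()
        expect = np.exp(0.2 + re.omega1[knot_id] + 0.3)
        assert np.allclose(surf.d[:, 0], expect)


class TestBiasCorrection:
    def test_no_random_effects_equals_plug_in(self):
        st = toy_stations(100, n_years=2, seed=2)
        cfg = ModelConfig(n_knots=3, fields_on=(), seed=0, compute_se=False)
        f = fit(st, cfg)
        plug = indices_from_surface(predict_density(f))
        corr = bias_correct_indices(f, n_draws=50, seed=0, stations=st)
        assert np.allclose(corr.index, plug.index)
        assert np.allclose(corr.eao, plug.eao)

    def test_lognormal_closed_form(self, small_sim, small_fit):
        # corrected index should match the lognormal mean computed from the
        # Laplace Gaussian itself: plug-in * exp(Var(p1+p2 at cell)/2)
        st = small_sim.stations
        f = small_fit
        ctx = LikelihoodContext(st, f.mesh, fields_on=f.config.fields_on,
                                range_km=f.field_params.range_km)
        params = dict(alpha1=f.alpha1, alpha2=f.alpha2, gamma1=f.gamma1,
                      gamma2=f.gamma2, cv=f.gamma_obs_cv,
                      sds={"omega1": f.field_params.sd_omega1,
                           "eps1": f.field_params.sd_eps1},
                      range_km=f.field_params.range_km)
        u_hat = ctx.u_from_realization(f.re_modes)
        _, _, cho, _ = ctx.inner_mode(params, u0=u_hat)
        L = np.tril(cho[0])
        cov = np.linalg.inv(L @ L.T)
        plug = predict_density(f)
        knot_id = f.mesh.grid_cells["knot_id"].to_numpy()
        ny = len(f.years)
        var = np.zeros((len(knot_id), ny))
        for t in range(ny):
            iw = ctx.offsets["omega1"] + knot_id
            ie = ctx.offsets["eps1"] + t * ctx.nk + knot_id
            var[:, t] = (cov[iw, iw] + cov[ie, ie] + 2 * cov[iw, ie])
        expect = (plug.d * np.exp(var / 2) * plug.cell_area[:, None]).sum(axis=0)
        corr = bias_correct_indices(f, n_draws=4000, seed=1, stations=st)
        assert np.allclose(corr.index, expect, rtol=0.05)
        assert np.all(corr.index >= indices_from_surface(plug).index)

    def test_se_shrinks_with_draws(self, small_sim, small_fit):
        st = small_sim.stations
        few = bias_correct_indices(small_fit, n_draws=100, seed=3, stations=st)
        many = bias_correct_indices(small_fit, n_draws=100, seed=4, stations=st)
        # draw SD estimates the sampling spread, not the MC error of the mean:
        # two independent runs agree within MC noise
        assert np.allclose(few.se_index, many.se_index, rtol=0.5)
        assert few.bias_corrected and np.all(few.se_index > 0)
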
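import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from conftest import toy_stations

from stdelta.covariates import CovariateBasis
from stdelta.fields import FieldParams, FieldRealization
from stdelta.geo import build_mesh
from stdelta.model import (
    LikelihoodContext,
    ModelConfig,
    ModelFit,
    _regress,
    cross_validate,
    fit,
    laplace_marginal_loglik,
    linear_predictors,
    observation_loglik,
    pearson_residuals,
    poisson_link,
)


class TestPoissonLink:
    def test_unit_effort_zero_predictors(self):
        r1, r2 = poisson_link(0.0, 0.0, 1.0)
        assert r1 == pytest.approx(1 - np.exp(-1), abs=1e-12)
        assert r2 == pytest.approx(1 / (1 - np.exp(-1)), abs=1e-12)

    def test_vanishing_density_limit(self):
        r1, r2 = poisson_link(-40.0, 0.0, 1.0)
        assert r1 < 1e-15
        assert r1 * r2 == pytest.approx(np.exp(-40.0), rel=1e-9)

    def test_expected_catch_identity(self, rng):
        # r1 * r2 = a * exp(p1 + p2) is exact algebra of the link
        p1 = rng.uniform(-8, 3, 1000)
        p2 = rng.uniform(-4, 4, 1000)
        a = np.exp(rng.uniform(-3, 1, 1000))
        r1, r2 = poisson_link(p1, p2, a)
        assert np.allclose(r1 * r2, a * np.exp(p1 + p2), rtol=1e-12)
        assert np.all((r1 > 0) & (r1 < 1))

    def test_rejects_zero_effort(self):
        with pytest.raises(ValueError):
            poisson_link(0.0, 0.0, 0.0)


class TestObservationLoglik:
    def test_zero_catch_contributes_log_one_minus_r1(self):
        assert observation_loglik(0.0, 0.5, 2.0, 1.0) == pytest.approx(np.log(0.5))

    def test_exponential_special_case(self):
        # cv = 1 makes the gamma an exponential with scale r2
        ll = observation_loglik(2.0, 0.5, 2.0, 1.0)
        assert ll == pytest.approx(np.log(0.5) + np.log(0.5 * np.exp(-1.0)))

    def test_density_concentrates_at_mean_for_small_cv(self):
        at_mean = [observation_loglik(2.0, 0.5, 2.0, cv) for cv in (0.5, 0.2, 0.05)]
        assert np.all(np.diff(at_mean) > 0)

    def test_negative_catch_rejected(self):
        with pytest.raises(ValueError):
            observation_loglik(-1.0, 0.5, 1.0, 1.0)


def _plain_fit(stations, mesh, alpha1, alpha2, basis=None, gamma1=(), gamma2=(),
               cv=0.8, re=None, config=None):
    """Assemble a ModelFit by hand (no optimisation) for predictor tests."""
    years = np.sort(stations["year"].unique())
    nk = mesh.n_knots
    return ModelFit(
        years=years,
        alpha1=np.asarray(alpha1, dtype=float),
        alpha2=np.asarray(alpha2, dtype=float),
        gamma1=np.asarray(gamma1, dtype=float),
        gamma2=np.asarray(gamma2, dtype=float),
        field_params=FieldParams(range_km=150.0),
        gamma_obs_cv=cv,
        re_modes=re if re is not None else FieldRealization.zeros(nk, len(years)),
        logml=0.0, max_abs_grad=0.0, converged=True, at_bounds=False,
        mesh=mesh, basis=basis,
        config=config or ModelConfig(fields_on=(), compute_se=False),
        param_names=[], theta=np.zeros(0),
    )


class TestLinearPredictors:
    def test_all_effects_zero(self):
        st = toy_stations(20, n_years=2)
        mesh = build_mesh(st, 4, buffer_km=50, seed=0)
        f = _plain_fit(st, mesh, [0.0, 0.0], [0.0, 0.0])
        p1, p2 = linear_predictors(f, st)
        assert np.allclose(p1, 0.0) and np.allclose(p2, 0.0)

    def test_single_linear_covariate_arithmetic(self):
        st = toy_stations(10)
        st["x"] = 2.0
        mesh = build_mesh(st, 2, buffer_km=50, seed=0)
        basis = CovariateBasis(name="x", form="linear", transform="identity",
                               center=0.0, scale=1.0, knot_points=(0.0, 4.0))
        f = _plain_fit(st, mesh, [1.0], [0.0], basis=basis,
                       gamma1=[0.5], gamma2=[0.0])
        p1, _ = linear_predictors(f, st)
        assert np.allclose(p1, 2.0)  # alpha + gamma * x = 1 + 0.5 * 2

    def test_spline_covariate_matches_direct_matrix_product(self, rng):
        st = toy_stations(30)
        st["x"] = rng.uniform(5, 15, len(st))
        mesh = build_mesh(st, 3, buffer_km=50, seed=0)
        from stdelta.covariates import build_basis
        basis = build_basis(st["x"].to_numpy(), form="spline2df", name="x")
        gamma1 = np.array([0.7, -0.3])
        f = _plain_fit(st, mesh, [0.5], [0.0], basis=basis, gamma1=gamma1,
                       gamma2=[0.0, 0.0])
        p1, _ = linear_predictors(f, st)
        assert np.allclose(p1, 0.5 + basis.design(st["x"].to_numpy()) @ gamma1)


class TestLaplace:
    def test_no_random_effects_is_exact_loglik(self):
        st = toy_stations(80, seed=4)
        mesh = build_mesh(st, 4, buffer_km=50, seed=0)
        params = dict(alpha1=np.array([0.3]), alpha2=np.array([1.2]),
                      sds={}, range_km=100.0, cv=0.9)
        logml, re = laplace_marginal_loglik(params, st, mesh, fields_on=())
        a = st["area_swept"].to_numpy()
        r1, r2 = poisson_link(np.full(len(st), 0.3), np.full(len(st), 1.2), a)
        expect = observation_loglik(st["catch"].to_numpy(), r1, r2, 0.9).sum()
        assert logml == pytest.approx(expect, rel=1e-12)
        assert not re.omega1.any()

    def _quad_oracle(self, ctx, st, params):
        """Adaptive 1-D quadrature over a single spatial random effect."""
        a = st["area_swept"].to_numpy()
        c = st["catch"].to_numpy()
        sd = params["sds"]["omega1"] * np.sqrt(1 + 1e-8)  # basis jitter

        def joint(om):
            r1, r2 = poisson_link(np.full(len(c), params["alpha1"][0] + om),
                                  np.full(len(c), params["alpha2"][0]), a)
            ll = observation_loglik(c, r1, r2, params["cv"]).sum()
            return ll - 0.5 * np.log(2 * np.pi) - np.log(sd) - om**2 / (2 * sd**2)

        u, _, _, _ = ctx.inner_mode(params)
        mode = float(u[0])
        M = joint(mode)
        val, err = quad(lambda o: np.exp(joint(o) - M), mode - 4, mode + 4,
                        limit=200)
        assert err < 1e-9
        return M + np.log(val)

    def test_single_random_effect_matches_quadrature(self):
        st = toy_stations(2500, seed=8)
        mesh = build_mesh(st, 1, buffer_km=100, seed=0)
        ctx = LikelihoodContext(st, mesh, fields_on=("omega1",), range_km=100.0)
        params = dict(alpha1=np.array([0.5]), alpha2=np.array([1.0]),
                      gamma1=np.zeros(0), gamma2=np.zeros(0),
                      sds={"omega1": 0.5}, range_km=100.0, cv=0.8)
        logml, _, _ = ctx.laplace(params)
        assert logml == pytest.approx(self._quad_oracle(ctx, st, params), abs=1e-4)

    def test_duplicated_records_double_the_exact_loglik(self):
        st = toy_stations(60, seed=9)
        dup = st.copy()
        dup["station_id"] = dup["station_id"] + "_dup"
        both = pd.concat([st, dup], ignore_index=True)
        mesh = build_mesh(st, 3, buffer_km=50, seed=0)
        params = dict(alpha1=np.array([0.2]), alpha2=np.array([0.8]),
                      sds={}, range_km=100.0, cv=0.7)
        one, _ = laplace_marginal_loglik(params, st, mesh, fields_on=())
        two, _ = laplace_marginal_loglik(params, both, mesh, fields_on=())
        assert two == pytest.approx(2 * one, rel=1e-12)


class TestFit:
    def test_alpha_recovery_without_fields(self):
        # truth: no spatial structure, known year intercepts
        rng = np.random.default_rng(21)
        rows = []
        alpha1_true, alpha2_true = [0.5, 1.0], [1.5, 1.0]
        for t in range(2):
            for i in range(300):
                a = 0.2
                lam = a * np.exp(alpha1_true[t])
                r1 = 1 - np.exp(-lam)
                r2 = lam / r1 * np.exp(alpha2_true[t])
                c = rng.gamma(1 / 0.64, r2 * 0.64) if rng.random() < r1 else 0.0
                rows.append(dict(station_id=f"s{t}_{i}", year=2000 + t,
                                 lon=-170 + i * 0.01, lat=55.0 + t * 0.1,
                                 area_swept=a, catch=c))
        from stdelta.geo import validate_stations
        st = validate_stations(pd.DataFrame(rows))
        cfg = ModelConfig(n_knots=2, fields_on=(), seed=0)
        res = fit(st, cfg)
        assert res.converged
        for est, tru, name in [(res.alpha1, alpha1_true, "alpha1"),
                               (res.alpha2, alpha2_true, "alpha2")]:
            for j in range(2):
                se = res.se[f"{name}[{2000 + j}]"]
                assert abs(est[j] - tru[j]) < 3 * se, (name, j, est[j], tru[j], se)

    def test_record_order_invariance(self, small_sim):
        cfg = ModelConfig(n_knots=10, fields_on=("omega1", "eps1"),
                          seed=3, compute_se=False)
        st = small_sim.stations
        perm = st.sample(frac=1.0, random_state=7).reset_index(drop=True)
        f1 = fit(st, cfg, mesh=small_sim.mesh)
        f2 = fit(perm, cfg, mesh=small_sim.mesh)
        assert np.allclose(f1.theta, f2.theta, atol=1e-4)
        assert f1.logml == pytest.approx(f2.logml, abs=1e-4)

    def test_zero_encounter_year_flagged(self):
        st = toy_stations(40, n_years=2, seed=5)
        st.loc[st["year"] == 2001, "catch"] = 0.0
        cfg = ModelConfig(n_knots=2, fields_on=(), seed=0, compute_se=False)
        with pytest.warns(UserWarning, match="zero encounters"):
            res = fit(st, cfg)
        assert res.zero_encounter_years == [2001]

    def test_reported_gradient_verified_by_finite_differences(self, small_fit):
        assert small_fit.converged
        assert small_fit.max_abs_grad < 1e-3


class TestPearsonResiduals:
    def test_residual_formulas(self, small_sim, small_fit):
        st = small_sim.stations
        res = pearson_residuals(small_fit, st)
        p1, p2 = linear_predictors(small_fit, st)
        r1, r2 = poisson_link(p1, p2, st["area_swept"].to_numpy())
        c = st["catch"].to_numpy()
        enc = (c > 0).astype(float)
        expect = (enc - r1) / np.sqrt(r1 * (1 - r1))
        assert np.allclose(res["residual_encounter"], expect, equal_nan=True)
        pos = c > 0
        expect_pos = (c[pos] - r2[pos]) / (r2[pos] * small_fit.gamma_obs_cv)
        assert np.allclose(res.loc[pos, "residual_positive"], expect_pos)
        assert res.loc[~pos, "residual_positive"].isna().all()

    def test_unit_variance_at_true_parameters(self, small_sim):
        # at the generating parameters the encounter residuals have variance 1
        truth = small_sim.truth
        mesh = small_sim.mesh
        st = small_sim.stations
        f = _plain_fit(st, mesh, truth["alpha1"], truth["alpha2"],
                       cv=truth["obs_cv"], re=truth["fields"],
                       config=ModelConfig(fields_on=("omega1", "eps1")))
        res = pearson_residuals(f, st)
        v = np.nanvar(res["residual_encounter"])
        assert v == pytest.approx(1.0, abs=0.15)


class TestCrossValidation:
    def test_regression_identities(self, rng):
        y = rng.normal(0, 1, 100)
        perfect = _regress(y, y)
        assert perfect["slope"] == pytest.approx(1.0)
        assert perfect["r2"] == pytest.approx(1.0)
        constant = _regress(y, np.full(100, 3.0))
        assert constant["r2"] == 0.0

    def test_threefold_structure(self, small_sim):
        cfg = ModelConfig(n_knots=10, fields_on=("omega1", "eps1"),
                          seed=3, compute_se=False)
        out = cross_validate(small_sim.stations, cfg, n_folds=3, seed=1)
        assert len(out["folds"]) == 3
        assert out["in_sample"]["r2"] <= 1.0
        assert np.isfinite(out["out_sample"]["r2"])
        assert out["in_sample"]["n"] == len(small_sim.stations)
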
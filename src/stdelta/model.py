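"""Poisson-link delta GLMM with spatial / spatio-temporal Gaussian random fields.

The observation model is a two-part ("delta") model in the Poisson-link
parameterisation.  Two linear predictors per sample i,

    p1_i = alpha1_{t_i} + omega1(s_i) + eps1(s_i, t_i) + X_i . gamma1
    p2_i = alpha2_{t_i} + omega2(s_i) + eps2(s_i, t_i) + X_i . gamma2

represent log number density and log biomass-per-group.  With area swept
a_i they induce an encounter probability and a positive catch rate

    r1_i = 1 - exp(-a_i * exp(p1_i))
    r2_i = a_i * exp(p1_i) / r1_i * exp(p2_i)

so that E[catch] = r1 * r2 = a * exp(p1 + p2).  Zero catches contribute
log(1 - r1); positive catches contribute log(r1) plus a gamma density with
mean r2 and a shared coefficient of variation.

The random fields (omega spatial, epsilon spatio-temporal, independent
across years) live at mesh knots with Matérn correlation and are integrated
out by a Laplace approximation: an inner Newton optimisation finds the joint
mode over all random effects, and the marginal log likelihood is the joint
log density at the mode plus half the log determinant of 2*pi times the
inverse curvature.  Fixed effects, field SDs (log scale) and the gamma CV
(log scale) are then maximised by quasi-Newton with finite-difference
gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import gammaln

from .covariates import CovariateBasis, build_basis
from .fields import FieldParams, FieldRealization, correlation_precision
from .geo import SpatialMesh, build_mesh, validate_stations

__all__ = [
    "ModelConfig",
    "ModelFit",
    "fit",
    "poisson_link",
    "observation_loglik",
    "linear_predictors",
    "laplace_marginal_loglik",
    "pearson_residuals",
    "cross_validate",
]

_FIELD_ORDER = ("omega1", "omega2", "eps1", "eps2")

# exponent cap: lambda = a*exp(p1) saturates instead of overflowing
_LOG_LAM_MAX = 30.0


# ---------------------------------------------------------------------------
# configuration and fit containers


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate entering the linear predictors.

    form: 'linear' (one z-scored column) or 'spline2df' (quadratic B-spline,
    no interior knot, 2 columns).  transform: 'identity' or 'log1p'.
    """

    name: str
    form: str = "linear"
    transform: str = "identity"

    def __post_init__(self):
        if self.form not in ("linear", "spline2df"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.transform not in ("identity", "log1p"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass(frozen=True)
class ModelConfig:
    """Model structure and fitting controls.

    One covariate per fitted model (covariate comparison is done across
    separate fits).  ``fields_on`` selects which random fields are active;
    the correlation range is shared across fields and fixed at ``range_km``
    unless ``estimate_range`` is set.
    """

    covariate: Optional[CovariateSpec] = None
    covariate_in_p2: bool = True
    n_knots: int = 25
    buffer_km: float = 25.0
    grid_spacing_km: float = 10.0
    fields_on: Sequence[str] = _FIELD_ORDER
    range_km: float = 150.0
    estimate_range: bool = False
    sd_init: float = 0.5
    cv_init: float = 0.8
    gradient_tol: float = 1e-3
    inner_tol: float = 1e-7
    maxiter: int = 500
    seed: int = 0
    compute_se: bool = True

    def __post_init__(self):
        bad = set(self.fields_on) - set(_FIELD_ORDER)
        if bad:
            raise ValueError(f"unknown fields {sorted(bad)}")
        object.__setattr__(self, "fields_on", tuple(f for f in _FIELD_ORDER if f in self.fields_on))

    def with_(self, **kw) -> "ModelConfig":
        return replace(self, **kw)


@dataclass
class ModelFit:
    """Maximum-likelihood fit of the spatio-temporal delta model."""

    years: np.ndarray
    alpha1: np.ndarray
    alpha2: np.ndarray
    gamma1: np.ndarray
    gamma2: np.ndarray
    field_params: FieldParams
    gamma_obs_cv: float
    re_modes: FieldRealization
    logml: float
    max_abs_grad: float
    converged: bool
    at_bounds: bool
    mesh: SpatialMesh
    basis: Optional[CovariateBasis]
    config: ModelConfig
    param_names: list
    theta: np.ndarray
    cov_params: Optional[np.ndarray] = None
    se: Optional[dict] = None
    zero_encounter_years: list = field(default_factory=list)
    n_records: int = 0

    def gamma1_cov(self) -> Optional[np.ndarray]:
        """Wald covariance block of the p1 covariate coefficients."""
        if self.cov_params is None:
            return None
        idx = [i for i, n in enumerate(self.param_names) if n.startswith("gamma1")]
        return self.cov_params[np.ix_(idx, idx)]

    def summary(self) -> dict:
        fp = self.field_params
        return {
            "logml": self.logml,
            "max_abs_grad": self.max_abs_grad,
            "converged": self.converged,
            "alpha1": self.alpha1.tolist(),
            "alpha2": self.alpha2.tolist(),
            "gamma1": self.gamma1.tolist(),
            "gamma2": self.gamma2.tolist(),
            "sd_omega1": fp.sd_omega1,
            "sd_omega2": fp.sd_omega2,
            "sd_eps1": fp.sd_eps1,
            "sd_eps2": fp.sd_eps2,
            "range_km": fp.range_km,
            "gamma_obs_cv": self.gamma_obs_cv,
            "zero_encounter_years": self.zero_encounter_years,
        }


# ---------------------------------------------------------------------------
# link and observation model


def poisson_link(p1, p2, area_swept):
    """Encounter probability r1 and positive catch rate r2 from (p1, p2, a).

    r1 = 1 - exp(-a e^{p1});  r2 = a e^{p1} / r1 * e^{p2}.  Computed via
    expm1/log1p so extreme predictors neither overflow nor lose precision.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    a = np.asarray(area_swept, dtype=float)
    if np.any(a <= 0):
        raise ValueError("area_swept must be > 0")
    log_lam = np.clip(np.log(a) + p1, -700.0, _LOG_LAM_MAX)
    lam = np.exp(log_lam)
    r1 = -np.expm1(-lam)
    log_r1 = np.log(r1)
    r2 = np.exp(log_lam - log_r1 + p2)
    return r1[()], r2[()]


def observation_loglik(catch, r1, r2, gamma_obs_cv):
    """Per-record delta-gamma log likelihood.

    Zero catch: log(1 - r1).  Positive catch: log(r1) + gamma log density
    with mean r2 and CV ``gamma_obs_cv`` (shape 1/cv^2, scale r2*cv^2).
    """
    c = np.asarray(catch, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any(c < 0):
        raise ValueError("catch must be >= 0")
    if gamma_obs_cv <= 0:
        raise ValueError("gamma_obs_cv must be > 0")
    k = 1.0 / gamma_obs_cv**2
    out = np.where(c > 0, 0.0, np.log1p(-np.minimum(r1, 1.0 - 1e-16)))
    pos = c > 0
    if np.any(pos):
        scale = r2 * gamma_obs_cv**2
        lg = (
            (k - 1.0) * np.log(c, where=pos, out=np.zeros_like(c))
            - c / scale
            - k * np.log(scale)
            - gammaln(k)
        )
        out = np.where(pos, np.log(r1) + lg, out)
    return out[()]


def _obs_derivs(p1, p2, a, c, cv, log_c, log_a=None, order=2):
    """Delta-gamma log likelihood and derivatives w.r.t. (p1, p2).

    Returns (ll_sum, d1, d2, d11, d12, d22); derivative arrays are None when
    ``order`` < their order.  Vectorised over records; zero-catch records
    contribute only through p1.
    """
    k = 1.0 / cv**2
    beta = 1.0 + k
    if log_a is None:
        log_a = np.log(a)
    log_lam = np.clip(log_a + p1, -700.0, _LOG_LAM_MAX)
    lam = np.exp(log_lam)
    elam = np.exp(-lam)
    r1 = -np.expm1(-lam)
    pos = c > 0

    s = np.clip(p1 + p2, -700.0, 700.0)
    es = np.exp(-s)
    m = c / (a * cv**2)
    log_r1 = np.log(np.maximum(r1, 1e-300))
    mr1es = m * r1 * es

    ll = np.where(
        pos,
        beta * log_r1 - k * s - k * log_a - 2.0 * k * np.log(cv)
        + (k - 1.0) * log_c - gammaln(k) - mr1es,
        -lam,
    )
    ll_sum = float(np.sum(ll))
    if order < 1:
        return ll_sum, None, None, None, None, None

    r1p = lam * elam
    w = r1p / np.maximum(r1, 1e-300)
    d1 = np.where(pos, beta * w - k - m * es * (r1p - r1), -lam)
    d2 = np.where(pos, -k + mr1es, 0.0)
    if order < 2:
        return ll_sum, d1, d2, None, None, None

    r1pp = lam * (1.0 - lam) * elam
    wp = r1pp / np.maximum(r1, 1e-300) - w**2
    d11 = np.where(pos, beta * wp - m * es * (r1pp - 2.0 * r1p + r1), -lam)
    d12 = np.where(pos, m * es * (r1p - r1), 0.0)
    d22 = np.where(pos, -mr1es, 0.0)
    return ll_sum, d1, d2, d11, d12, d22


# ---------------------------------------------------------------------------
# likelihood context: data layout, random-effect indexing, Laplace machinery


class LikelihoodContext:
    """Precomputed data structures for one dataset / mesh / basis combination.

    Random effects are stacked as u = [omega1 | omega2 | eps1 | eps2]
    (active fields only), epsilon stored year-major (index t*n_knots + k) so
    the prior precision is block diagonal per year.
    """

    def __init__(self, stations, mesh, basis=None, fields_on=_FIELD_ORDER,
                 covariate_in_p2=True, range_km=150.0):
        self.mesh = mesh
        self.basis = basis
        self.covariate_in_p2 = bool(covariate_in_p2)
        self.years = np.sort(np.unique(stations["year"].to_numpy()))
        self.ny = len(self.years)
        self.nk = mesh.n_knots
        year_pos = {y: i for i, y in enumerate(self.years)}
        self.t = np.array([year_pos[y] for y in stations["year"].to_numpy()])
        xy = stations[["easting_km", "northing_km"]].to_numpy(dtype=float)
        self.k = mesh.assign(xy)
        self.a = stations["area_swept"].to_numpy(dtype=float)
        self.log_a = np.log(self.a)
        self.c = stations["catch"].to_numpy(dtype=float)
        self.log_c = np.where(self.c > 0, np.log(np.maximum(self.c, 1e-300)), 0.0)
        self.n = len(stations)
        if basis is not None:
            vals = stations[basis.name].to_numpy(dtype=float)
            if np.any(~np.isfinite(vals)):
                raise ValueError(
                    f"covariate {basis.name!r} has missing values; fill before fitting"
                )
            self.X = basis.design(vals)
        else:
            self.X = np.zeros((self.n, 0))
        self.ncol = self.X.shape[1]
        self.fields_on = tuple(f for f in _FIELD_ORDER if f in fields_on)
        self.range_km = float(range_km)
        self._prec_cache = {}

        # random-effect layout
        self.offsets = {}
        off = 0
        for f in self.fields_on:
            size = self.nk if f.startswith("omega") else self.nk * self.ny
            self.offsets[f] = off
            off += size
        self.n_u = off

        # per-record loading indices into u for each predictor
        self.J1, self.J2 = [], []
        if "omega1" in self.offsets:
            self.J1.append(self.offsets["omega1"] + self.k)
        if "eps1" in self.offsets:
            self.J1.append(self.offsets["eps1"] + self.t * self.nk + self.k)
        if "omega2" in self.offsets:
            self.J2.append(self.offsets["omega2"] + self.k)
        if "eps2" in self.offsets:
            self.J2.append(self.offsets["eps2"] + self.t * self.nk + self.k)

        # flattened Hessian scatter pattern (fixed; weights vary per step)
        pairs, groups = [], []
        for i in self.J1:
            for j in self.J1:
                pairs.append(i * self.n_u + j)
                groups.append("d11")
        for i in self.J2:
            for j in self.J2:
                pairs.append(i * self.n_u + j)
                groups.append("d22")
        for i in self.J1:
            for j in self.J2:
                pairs.append(i * self.n_u + j)
                groups.append("d12")
                pairs.append(j * self.n_u + i)
                groups.append("d12")
        self._hess_idx = np.concatenate(pairs) if pairs else np.zeros(0, dtype=int)
        self._hess_groups = groups

    # -- parameter vector layout -------------------------------------------

    def param_names(self, estimate_range=False):
        names = [f"alpha1[{y}]" for y in self.years]
        names += [f"alpha2[{y}]" for y in self.years]
        names += [f"gamma1[{j}]" for j in range(self.ncol)]
        if self.covariate_in_p2:
            names += [f"gamma2[{j}]" for j in range(self.ncol)]
        names += [f"log_sd_{f}" for f in self.fields_on]
        if estimate_range:
            names += ["log_range"]
        names += ["log_cv"]
        return names

    def unpack(self, theta, estimate_range=False):
        ny, nc = self.ny, self.ncol
        pos = 0
        alpha1 = theta[pos:pos + ny]; pos += ny
        alpha2 = theta[pos:pos + ny]; pos += ny
        gamma1 = theta[pos:pos + nc]; pos += nc
        if self.covariate_in_p2:
            gamma2 = theta[pos:pos + nc]; pos += nc
        else:
            gamma2 = np.zeros(nc)
        sds = {}
        for f in self.fields_on:
            sds[f] = np.exp(theta[pos]); pos += 1
        rng = np.exp(theta[pos]) if estimate_range else self.range_km
        if estimate_range:
            pos += 1
        cv = np.exp(theta[pos]); pos += 1
        assert pos == len(theta)
        return dict(alpha1=alpha1, alpha2=alpha2, gamma1=gamma1, gamma2=gamma2,
                    sds=sds, range_km=rng, cv=cv)

    # -- prior precision ----------------------------------------------------

    def _corr_precision(self, range_km):
        key = round(float(range_km), 10)
        if key not in self._prec_cache:
            if len(self._prec_cache) > 64:
                self._prec_cache.clear()
            self._prec_cache[key] = correlation_precision(self.mesh.knots, range_km)
        return self._prec_cache[key]

    def prior(self, sds, range_km):
        """Dense prior precision over u and the MVN normalising constant."""
        nk, ny = self.nk, self.ny
        P = np.zeros((self.n_u, self.n_u))
        const = 0.0
        if self.n_u == 0:
            return P, const
        Q, logdet_corr = self._corr_precision(range_km)
        for f in self.fields_on:
            sd = max(sds[f], 1e-12)
            off = self.offsets[f]
            block = Q / sd**2
            if f.startswith("omega"):
                P[off:off + nk, off:off + nk] = block
                const += 0.5 * nk * np.log(2 * np.pi) + nk * np.log(sd) + 0.5 * logdet_corr
            else:
                for tt in range(ny):
                    o = off + tt * nk
                    P[o:o + nk, o:o + nk] = block
                const += ny * (0.5 * nk * np.log(2 * np.pi) + nk * np.log(sd)
                               + 0.5 * logdet_corr)
        return P, const

    # -- joint negative log likelihood over random effects ------------------

    def predictors(self, params, u):
        p1 = params["alpha1"][self.t] + self.X @ params["gamma1"]
        p2 = params["alpha2"][self.t] + self.X @ params["gamma2"]
        for idx in self.J1:
            p1 = p1 + u[idx]
        for idx in self.J2:
            p2 = p2 + u[idx]
        return p1, p2

    def _fgh(self, params, u, P, const, order=2):
        p1, p2 = self.predictors(params, u)
        ll, d1, d2, d11, d12, d22 = _obs_derivs(
            p1, p2, self.a, self.c, params["cv"], self.log_c, log_a=self.log_a, order=order
        )
        Pu = P @ u
        f = -ll + 0.5 * float(u @ Pu) + const
        if order < 1:
            return f, None, None
        g = Pu.copy()
        for idx in self.J1:
            g -= np.bincount(idx, weights=d1, minlength=self.n_u)
        for idx in self.J2:
            g -= np.bincount(idx, weights=d2, minlength=self.n_u)
        if order < 2:
            return f, g, None
        w = {"d11": -d11, "d22": -d22, "d12": -d12}
        weights = np.concatenate([w[gname] for gname in self._hess_groups]) \
            if self._hess_groups else np.zeros(0)
        Hdata = np.bincount(self._hess_idx, weights=weights,
                            minlength=self.n_u * self.n_u).reshape(self.n_u, self.n_u)
        return f, g, P + Hdata

    def inner_mode(self, params, u0=None, tol=1e-8, max_newton=100):
        """Newton optimisation of the joint negative log likelihood over u.

        Returns (u_hat, f_hat, cho_H, n_iter).  Damped steps (ridge plus step
        halving) guard the rare non-PD or overshooting iteration.
        """
        P, const = self.prior(params["sds"], params["range_km"])
        if self.n_u == 0:
            f, _, _ = self._fgh(params, np.zeros(0), P, const, order=0)
            return np.zeros(0), f, None, 0
        u = np.zeros(self.n_u)
        if u0 is not None:
            # a stale warm start can be worse than a cold one; take the better
            f_zero, _, _ = self._fgh(params, u, P, const, order=0)
            f_warm, _, _ = self._fgh(params, u0, P, const, order=0)
            if np.isfinite(f_warm) and f_warm < f_zero:
                u = u0.copy()
        f, g, H = self._fgh(params, u, P, const)
        eye = np.eye(self.n_u)
        it = 0
        restarted = u0 is None or not np.any(u)
        for it in range(1, max_newton + 1):
            gmax = np.max(np.abs(g))
            if gmax < tol:
                break
            # damped Newton: inflate the ridge until the factorisation exists
            # and the step is a descent direction
            ridge = 0.0
            scale = max(float(np.max(np.abs(np.diag(H)))), 1.0)
            while True:
                try:
                    cho = cho_factor(H + ridge * eye, lower=True)
                    step = cho_solve(cho, g)
                    gdot = float(g @ step)
                    if gdot > 0:
                        break
                except np.linalg.LinAlgError:
                    pass
                ridge = max(ridge * 10.0, 1e-6 * scale)
                if ridge > 1e12 * scale:
                    step = g / scale
                    gdot = float(g @ step)
                    break
            t = 1.0
            improved = False
            for _ in range(40):
                f_new, _, _ = self._fgh(params, u - t * step, P, const, order=0)
                if f_new <= f - 1e-4 * t * gdot:
                    improved = True
                    break
                if t == 1.0 and f_new <= f + 1e-9 * (1.0 + abs(f)):
                    # quadratic-convergence regime: the decrease is below the
                    # float resolution of f; take the full Newton step
                    improved = True
                    break
                t *= 0.5
            if not improved:
                if restarted:
                    break  # stalled from a cold start; return current point
                u = np.zeros(self.n_u)  # stalled warm start: retry cold
                restarted = True
            else:
                u = u - t * step
            f, g, H = self._fgh(params, u, P, const)
        ridge = 0.0
        scale = max(float(np.max(np.abs(np.diag(H)))), 1.0)
        while True:
            try:
                cho = cho_factor(H + ridge * eye, lower=True)
                break
            except np.linalg.LinAlgError:
                ridge = max(ridge * 10.0, 1e-8 * scale)
        return u, f, cho, it

    def laplace(self, params, u0=None, tol=1e-8):
        """Laplace-approximated marginal log likelihood.

        logml = -f(u_hat) + (n_u/2) log(2 pi) - (1/2) log det H, with H the
        curvature of the joint negative log likelihood at the inner mode.
        Exact when n_u = 0 (no random effects).
        """
        u_hat, f_hat, cho, _ = self.inner_mode(params, u0=u0, tol=tol)
        if self.n_u == 0:
            return -f_hat, u_hat, cho
        logdetH = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        logml = -f_hat + 0.5 * self.n_u * np.log(2 * np.pi) - 0.5 * logdetH
        return logml, u_hat, cho

    def realization_from_u(self, u) -> FieldRealization:
        nk, ny = self.nk, self.ny
        out = FieldRealization.zeros(nk, ny)
        for f in self.fields_on:
            off = self.offsets[f]
            if f.startswith("omega"):
                setattr(out, f, u[off:off + nk].copy())
            else:
                setattr(out, f, u[off:off + nk * ny].reshape(ny, nk).T.copy())
        return out

    def u_from_realization(self, real: FieldRealization) -> np.ndarray:
        u = np.zeros(self.n_u)
        for f in self.fields_on:
            off = self.offsets[f]
            vals = getattr(real, f)
            if f.startswith("omega"):
                u[off:off + self.nk] = vals
            else:
                u[off:off + self.nk * self.ny] = np.asarray(vals).T.ravel()
        return u


# ---------------------------------------------------------------------------
# public operations


def linear_predictors(fit: ModelFit, stations: pd.DataFrame, basis=None):
    """(p1, p2) at station rows from a fitted model (nearest-knot projection)."""
    basis = basis if basis is not None else fit.basis
    ctx = LikelihoodContext(
        stations, fit.mesh, basis=basis,
        fields_on=tuple(f for f in _FIELD_ORDER
                        if f in fit.config.fields_on),
        covariate_in_p2=fit.config.covariate_in_p2,
        range_km=fit.field_params.range_km,
    )
    missing_years = set(ctx.years) - set(fit.years)
    if missing_years:
        raise ValueError(f"years not in fit: {sorted(missing_years)}")
    pos = {y: i for i, y in enumerate(fit.years)}
    sel = np.array([pos[y] for y in ctx.years])
    params = dict(
        alpha1=fit.alpha1[sel], alpha2=fit.alpha2[sel],
        gamma1=fit.gamma1, gamma2=fit.gamma2,
        cv=fit.gamma_obs_cv,
    )
    # re-map epsilon columns to the prediction years
    real = fit.re_modes
    sub = FieldRealization(
        omega1=real.omega1, omega2=real.omega2,
        eps1=real.eps1[:, sel], eps2=real.eps2[:, sel],
    )
    u = ctx.u_from_realization(sub)
    return ctx.predictors(params, u)


def laplace_marginal_loglik(fixed_params: dict, stations, mesh, basis=None,
                            fields_on=_FIELD_ORDER, covariate_in_p2=True):
    """Marginal log likelihood and random-effect modes at given fixed parameters.

    ``fixed_params`` needs alpha1, alpha2 (per year, sorted), gamma1, gamma2,
    sds (dict per active field), range_km, cv.
    """
    ctx = LikelihoodContext(stations, mesh, basis=basis, fields_on=fields_on,
                            covariate_in_p2=covariate_in_p2,
                            range_km=fixed_params.get("range_km", 150.0))
    params = dict(fixed_params)
    params.setdefault("gamma1", np.zeros(ctx.ncol))
    params.setdefault("gamma2", np.zeros(ctx.ncol))
    params["alpha1"] = np.asarray(params["alpha1"], dtype=float)
    params["alpha2"] = np.asarray(params["alpha2"], dtype=float)
    params["gamma1"] = np.asarray(params["gamma1"], dtype=float)
    params["gamma2"] = np.asarray(params["gamma2"], dtype=float)
    logml, u_hat, _ = ctx.laplace(params)
    return logml, ctx.realization_from_u(u_hat)


def _starting_theta(ctx: LikelihoodContext, config: ModelConfig):
    """Year intercepts by inverting the link at yearly encounter rates and
    positive-catch means; variances at log(sd_init)."""
    theta = []
    a1 = np.zeros(ctx.ny)
    a2 = np.zeros(ctx.ny)
    for tt in range(ctx.ny):
        sel = ctx.t == tt
        enc = float(np.clip(np.mean(ctx.c[sel] > 0), 0.02, 0.98))
        lam = -np.log1p(-enc)
        mean_a = float(np.mean(ctx.a[sel]))
        a1[tt] = np.log(lam / mean_a)
        pos = ctx.c[sel][ctx.c[sel] > 0]
        r2 = float(np.mean(pos)) if len(pos) else 1.0
        # r2 = a e^{p1} / r1 * e^{p2}  =>  p2 = log r2 + log r1 - log lam
        a2[tt] = np.log(max(r2, 1e-3)) + np.log(enc) - np.log(lam)
    theta += list(a1)
    theta += list(a2)
    theta += [0.0] * ctx.ncol
    if ctx.covariate_in_p2:
        theta += [0.0] * ctx.ncol
    theta += [np.log(config.sd_init)] * len(ctx.fields_on)
    if config.estimate_range:
        theta += [np.log(config.range_km)]
    theta += [np.log(config.cv_init)]
    return np.array(theta)


def _bounds(ctx: LikelihoodContext, config: ModelConfig):
    b = [(-30.0, 30.0)] * (2 * ctx.ny)
    ngam = ctx.ncol * (2 if ctx.covariate_in_p2 else 1)
    b += [(-30.0, 30.0)] * ngam
    b += [(-6.0, 2.5)] * len(ctx.fields_on)
    if config.estimate_range:
        b += [(np.log(10.0), np.log(2000.0))]
    b += [(-4.0, 2.5)]
    return b


def _fd_gradient(fun, theta, h=1e-5):
    g = np.zeros_like(theta)
    for i in range(len(theta)):
        hi = h * (1.0 + abs(theta[i]))
        e = np.zeros_like(theta)
        e[i] = hi
        g[i] = (fun(theta + e) - fun(theta - e)) / (2 * hi)
    return g


def _fd_hessian(fun, theta, h=1e-3):
    p = len(theta)
    H = np.zeros((p, p))
    f0 = fun(theta)
    hs = h * (1.0 + np.abs(theta))
    for i in range(p):
        ei = np.zeros(p); ei[i] = hs[i]
        fp = fun(theta + ei)
        fm = fun(theta - ei)
        H[i, i] = (fp + fm - 2 * f0) / hs[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p); ej[j] = hs[j]
            fpp = fun(theta + ei + ej)
            fpm = fun(theta + ei - ej)
            fmp = fun(theta - ei + ej)
            fmm = fun(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hs[i] * hs[j])
    return H


def fit(stations: pd.DataFrame, config: ModelConfig,
        mesh: Optional[SpatialMesh] = None) -> ModelFit:
    """Maximise the Laplace marginal likelihood over fixed parameters.

    Builds the knot mesh (k-means, seeded from the config) and covariate
    basis if not supplied, then runs bounded quasi-Newton (L-BFGS-B) with
    finite-difference gradients, warm-starting the inner random-effect mode
    between evaluations.  Convergence requires the central-difference
    gradient of the marginal log likelihood below ``config.gradient_tol``
    with no parameter at its bound; a failure is reported on the fit, never
    silently accepted.
    """
    if "easting_km" not in stations.columns:
        stations = validate_stations(stations)
    if stations["year"].nunique() < 2:
        raise ValueError("need at least 2 years of data")
    if mesh is None:
        mesh = build_mesh(stations, config.n_knots, buffer_km=config.buffer_km,
                          seed=config.seed, grid_spacing_km=config.grid_spacing_km)
    basis = None
    if config.covariate is not None:
        cs = config.covariate
        basis = build_basis(stations[cs.name].to_numpy(dtype=float),
                            form=cs.form, transform=cs.transform, name=cs.name)
    ctx = LikelihoodContext(stations, mesh, basis=basis,
                            fields_on=config.fields_on,
                            covariate_in_p2=config.covariate_in_p2,
                            range_km=config.range_km)

    zero_enc = [int(y) for i, y in enumerate(ctx.years)
                if not np.any(ctx.c[ctx.t == i] > 0)]
    if zero_enc:
        warnings.warn(f"years with zero encounters (weakly identified intercepts): {zero_enc}")

    cache = {"u": None}

    def negloglik(theta):
        params = ctx.unpack(theta, estimate_range=config.estimate_range)
        logml, u_hat, _ = ctx.laplace(params, u0=cache["u"], tol=config.inner_tol)
        cache["u"] = u_hat
        return -logml

    # optimise the per-record-scaled objective: with O(1) gradients the
    # quasi-Newton line search cannot be catapulted onto the bounds corner
    # by its unit initial Hessian scaling
    scale = 1.0 / ctx.n

    def negloglik_grad(theta):
        # central differences with a warm-started inner solve per evaluation;
        # scipy's one-sided internal differencing is too noisy for the line
        # search once the objective spans many orders of magnitude
        f = negloglik(theta)
        g = _fd_gradient(negloglik, theta, h=1e-5)
        return scale * f, scale * g

    theta0 = _starting_theta(ctx, config)
    bounds = _bounds(ctx, config)
    res = minimize(
        negloglik_grad, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
        options=dict(maxiter=config.maxiter, maxfun=10 * config.maxiter * len(theta0),
                     ftol=1e-14, gtol=0.2 * config.gradient_tol * scale),
    )
    theta = res.x
    grad = _fd_gradient(negloglik, theta)
    max_abs_grad = float(np.max(np.abs(grad)))
    at_bounds = any(
        (abs(t - lo) < 1e-8 or abs(t - hi) < 1e-8) for t, (lo, hi) in zip(theta, bounds)
    )
    converged = bool(max_abs_grad < config.gradient_tol and not at_bounds)
    if not converged:
        warnings.warn(
            f"fit did not meet convergence criteria: max|grad|={max_abs_grad:.2e}, "
            f"at_bounds={at_bounds}"
        )

    params = ctx.unpack(theta, estimate_range=config.estimate_range)
    logml, u_hat, _ = ctx.laplace(params, u0=cache["u"], tol=config.inner_tol)
    cache["u"] = u_hat

    cov_params = None
    se = None
    names = ctx.param_names(estimate_range=config.estimate_range)
    if config.compute_se:
        H = _fd_hessian(negloglik, theta)
        try:
            cov_params = np.linalg.inv(H)
            if np.any(np.diag(cov_params) <= 0):
                raise np.linalg.LinAlgError("non-PD")
        except np.linalg.LinAlgError:
            warnings.warn("outer Hessian not positive definite; using pseudo-inverse")
            cov_params = np.linalg.pinv(H)
        se = {n: float(np.sqrt(max(v, 0.0)))
              for n, v in zip(names, np.diag(cov_params))}

    fp_kwargs = {f"sd_{f}": params["sds"].get(f, 0.0) for f in _FIELD_ORDER}
    field_params = FieldParams(range_km=params["range_km"], **fp_kwargs)
    return ModelFit(
        years=ctx.years,
        alpha1=params["alpha1"].copy(),
        alpha2=params["alpha2"].copy(),
        gamma1=params["gamma1"].copy(),
        gamma2=params["gamma2"].copy(),
        field_params=field_params,
        gamma_obs_cv=float(params["cv"]),
        re_modes=ctx.realization_from_u(u_hat),
        logml=float(logml),
        max_abs_grad=max_abs_grad,
        converged=converged,
        at_bounds=at_bounds,
        mesh=mesh,
        basis=basis,
        config=config,
        param_names=names,
        theta=theta.copy(),
        cov_params=cov_params,
        se=se,
        zero_encounter_years=zero_enc,
        n_records=ctx.n,
    )


def pearson_residuals(fit: ModelFit, stations: pd.DataFrame) -> pd.DataFrame:
    """Pearson residuals for the encounter and positive-catch components.

    Encounter: (1{catch>0} - r1) / sqrt(r1 (1 - r1)); positive (encountered
    records only): (catch - r2) / (r2 * cv).  Residuals where r1 is exactly
    0 or 1 are emitted as NaN.
    """
    if "easting_km" not in stations.columns:
        stations = validate_stations(stations)
    p1, p2 = linear_predictors(fit, stations)
    a = stations["area_swept"].to_numpy(dtype=float)
    c = stations["catch"].to_numpy(dtype=float)
    r1, r2 = poisson_link(p1, p2, a)
    enc = (c > 0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res_enc = (enc - r1) / np.sqrt(r1 * (1.0 - r1))
    res_enc = np.where((r1 <= 0) | (r1 >= 1), np.nan, res_enc)
    n_undef = int(np.sum(~np.isfinite(res_enc)))
    if n_undef:
        warnings.warn(f"{n_undef} encounter residuals undefined (r1 in {{0,1}})")
    res_pos = np.where(c > 0, (c - r2) / (r2 * fit.gamma_obs_cv), np.nan)
    return pd.DataFrame({
        "station_id": stations["station_id"].to_numpy(),
        "year": stations["year"].to_numpy(),
        "residual_encounter": res_enc,
        "residual_positive": res_pos,
    })


def _obs_vs_pred(fit: ModelFit, stations: pd.DataFrame) -> pd.DataFrame:
    p1, p2 = linear_predictors(fit, stations)
    pred = np.exp(np.clip(p1 + p2, -700, 700))  # density at unit effort
    obs = stations["catch"].to_numpy(dtype=float) / stations["area_swept"].to_numpy(dtype=float)
    return pd.DataFrame({"observed": obs, "predicted": pred})


def _regress(obs, pred):
    """OLS of observed on predicted: slope, intercept, R^2."""
    x = np.asarray(pred, dtype=float)
    y = np.asarray(obs, dtype=float)
    if len(x) < 3:
        return dict(slope=np.nan, intercept=np.nan, r2=np.nan, n=len(x))
    if np.var(x) == 0:
        # constant prediction explains nothing
        return dict(slope=np.nan, intercept=float(np.mean(y)), r2=0.0, n=len(x))
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return dict(slope=float(coef[1]), intercept=float(coef[0]), r2=r2, n=len(x))


def cross_validate(stations: pd.DataFrame, config: ModelConfig,
                   n_folds: int = 3, seed: int = 0) -> dict:
    """Simple random-design cross-validation of observed vs predicted density.

    Records are partitioned at random into ``n_folds`` folds; the model is
    refit on each training set (shared mesh from the full data) and held-out
    densities are regressed on predictions.  Folds without positive catches
    are flagged and excluded from the pooled out-of-sample regression.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if "easting_km" not in stations.columns:
        stations = validate_stations(stations)
    rng = np.random.default_rng(seed)
    n = len(stations)
    fold_of = rng.permutation(n) % n_folds
    mesh = build_mesh(stations, config.n_knots, buffer_km=config.buffer_km,
                      seed=config.seed, grid_spacing_km=config.grid_spacing_km)

    full_fit = fit(stations, config.with_(compute_se=False), mesh=mesh)
    in_sample = _regress(*_obs_vs_pred(full_fit, stations).T.to_numpy())

    folds = []
    pooled = []
    for f in range(n_folds):
        test = stations.iloc[fold_of == f]
        train = stations.iloc[fold_of != f]
        if not np.any(test["catch"].to_numpy() > 0) or not np.any(train["catch"].to_numpy() > 0):
            folds.append(dict(fold=f, flagged=True, slope=np.nan, intercept=np.nan,
                              r2=np.nan, n=len(test)))
            continue
        # drop test years absent from training (intercept unavailable)
        test = test[test["year"].isin(train["year"].unique())]
        fold_fit = fit(train, config.with_(compute_se=False), mesh=mesh)
        ov = _obs_vs_pred(fold_fit, test)
        stats = _regress(ov["observed"], ov["predicted"])
        stats.update(fold=f, flagged=False)
        folds.append(stats)
        pooled.append(ov)
    if pooled:
        allov = pd.concat(pooled, ignore_index=True)
        out_sample = _regress(allov["observed"], allov["predicted"])
    else:
        out_sample = dict(slope=np.nan, intercept=np.nan, r2=np.nan, n=0)
    return dict(in_sample=in_sample, out_sample=out_sample, folds=folds)
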
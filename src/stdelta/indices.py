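"""Density surfaces and annual indices: biomass, centre of gravity, area occupied.

Predicted density on the extrapolation grid is d(s,t) = r1 * r2 evaluated at
unit effort, i.e. catch per unit of area swept.  The annual quantities are

    I_t = sum_s a_s d(s,t)                       biomass index (kg)
    z_{t,m} = sum_s z_{s,m} a_s d(s,t) / I_t     centre of gravity (km)
    A_t = I_t / D_t                              effective area occupied (km^2)

where a_s is the cell area and D_t the biomass-weighted mean density
D_t = sum_s a_s d(s,t)^2 / I_t, so a uniform surface occupies the whole
modelled area and a point concentration occupies one cell.

Because d is a nonlinear (log-scale convex) function of the random effects,
the plug-in surface at the random-effect mode is biased low; the correction
here averages the derived quantities over draws of the random effects from
the Laplace Gaussian approximation at the mode, reporting the draw SD as the
standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .fields import FieldRealization
from .model import LikelihoodContext, ModelFit, _FIELD_ORDER

__all__ = [
    "DensitySurface",
    "AnnualIndices",
    "predict_density",
    "abundance_index",
    "center_of_gravity",
    "effective_area_occupied",
    "bias_correct_indices",
    "annual_index_table",
]


@dataclass
class DensitySurface:
    """Density d(s,t) on the extrapolation grid.

    d: (n_cells, n_years), kg per km^2 of area swept; cells with missing
    covariates hold NaN and are excluded from the indices.
    """

    cell_xy: np.ndarray     # (n_cells, 2) easting/northing km
    cell_area: np.ndarray   # (n_cells,) km^2
    years: np.ndarray
    d: np.ndarray           # (n_cells, n_years)

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.cell_area), len(self.years)):
            raise ValueError("density array does not conform to cells x years")
        with np.errstate(invalid="ignore"):
            if np.any(self.d[np.isfinite(self.d)] < 0):
                raise ValueError("density must be >= 0")

    @property
    def total_area(self) -> float:
        return float(np.sum(self.cell_area))

    def to_frame(self) -> pd.DataFrame:
        n_cells, n_years = self.d.shape
        return pd.DataFrame({
            "cell_id": np.repeat(np.arange(n_cells), n_years),
            "year": np.tile(self.years, n_cells),
            "x_km": np.repeat(self.cell_xy[:, 0], n_years),
            "y_km": np.repeat(self.cell_xy[:, 1], n_years),
            "area_km2": np.repeat(self.cell_area, n_years),
            "density": self.d.ravel(),
        })


@dataclass
class AnnualIndices:
    """Per-year index, centre of gravity and effective area occupied."""

    years: np.ndarray
    index: np.ndarray
    northing: np.ndarray
    easting: np.ndarray
    eao: np.ndarray
    se_index: np.ndarray | None = None
    se_northing: np.ndarray | None = None
    se_easting: np.ndarray | None = None
    se_eao: np.ndarray | None = None
    bias_corrected: bool = False

    def to_frame(self) -> pd.DataFrame:
        nan = np.full(len(self.years), np.nan)
        return pd.DataFrame({
            "year": self.years,
            "index": self.index,
            "se_index": self.se_index if self.se_index is not None else nan,
            "northing": self.northing,
            "se_northing": self.se_northing if self.se_northing is not None else nan,
            "easting": self.easting,
            "se_easting": self.se_easting if self.se_easting is not None else nan,
            "eao": self.eao,
            "se_eao": self.se_eao if self.se_eao is not None else nan,
        })


def _grid_design(fit: ModelFit, grid_covariates: pd.DataFrame | None):
    """Spline/linear design rows per (cell, year), or None for a field-only model."""
    if fit.basis is None:
        return None
    if grid_covariates is None:
        raise ValueError("model has a covariate; grid covariate values are required")
    n_cells = len(fit.mesh.grid_cells)
    piv = grid_covariates.pivot_table(index="cell_id", columns="year", values="value",
                                      aggfunc="first")
    piv = piv.reindex(index=np.arange(n_cells), columns=fit.years)
    vals = piv.to_numpy(dtype=float)  # (n_cells, n_years)
    miss = ~np.isfinite(vals)
    if miss.any():
        warnings.warn(f"{int(miss.sum())} grid cell-years missing covariate; "
                      "cells excluded from indices")
    out = np.full(vals.shape + (fit.basis.df,), np.nan)
    ok = np.isfinite(vals)
    if ok.any():
        out[ok] = fit.basis.design(vals[ok])
    return out


def predict_density(fit: ModelFit, grid_covariates: pd.DataFrame | None = None,
                    re: FieldRealization | None = None) -> DensitySurface:
    """Evaluate d = r1 * r2 at unit effort on every grid cell and year.

    Each cell inherits its knot's random-field values; ``re`` overrides the
    fitted random-effect modes (used by the bias-correction draws).  For a
    covariate model, ``grid_covariates`` provides (cell_id, year, value).
    """
    mesh = fit.mesh
    real = re if re is not None else fit.re_modes
    knot_id = mesh.grid_cells["knot_id"].to_numpy()
    ny = len(fit.years)
    p1 = fit.alpha1[None, :] + real.omega1[knot_id, None] + real.eps1[knot_id, :]
    p2 = fit.alpha2[None, :] + real.omega2[knot_id, None] + real.eps2[knot_id, :]
    B = _grid_design(fit, grid_covariates)
    if B is not None:
        p1 = p1 + B @ fit.gamma1
        p2 = p2 + B @ fit.gamma2
    # at unit effort r1*r2 = exp(p1+p2) exactly (Poisson-link identity)
    d = np.exp(np.clip(p1 + p2, -700, 700))
    if B is not None:
        d[np.isnan(B[..., 0])] = np.nan
    return DensitySurface(
        cell_xy=mesh.grid_cells[["x_km", "y_km"]].to_numpy(dtype=float),
        cell_area=mesh.grid_cells["area_km2"].to_numpy(dtype=float),
        years=fit.years.copy(),
        d=d,
    )


def _masked(surface: DensitySurface):
    d = surface.d
    ok = np.isfinite(d)
    dz = np.where(ok, d, 0.0)
    return dz, ok


def abundance_index(surface: DensitySurface) -> np.ndarray:
    """I_t = sum_s a_s d(s,t) per year."""
    dz, _ = _masked(surface)
    return surface.cell_area @ dz


def center_of_gravity(surface: DensitySurface):
    """Biomass-weighted mean location per year: (northing_t, easting_t) in km.

    Years with I_t = 0 are emitted as NaN.
    """
    dz, _ = _masked(surface)
    w = surface.cell_area[:, None] * dz
    I = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        easting = (surface.cell_xy[:, 0] @ w) / I
        northing = (surface.cell_xy[:, 1] @ w) / I
    easting = np.where(I > 0, easting, np.nan)
    northing = np.where(I > 0, northing, np.nan)
    return northing, easting


def effective_area_occupied(surface: DensitySurface, weighted: bool = True) -> np.ndarray:
    """A_t = I_t / D_t with D_t the biomass-weighted mean density.

    D_t = sum_s a_s d^2 / I_t, so A_t = I_t^2 / sum_s a_s d^2: the whole
    modelled area for a uniform surface, a single cell's area when all
    biomass sits in one cell.  ``weighted=False`` uses the unweighted mean
    density over occupied cells instead.
    """
    dz, ok = _masked(surface)
    I = surface.cell_area @ dz
    if weighted:
        denom = surface.cell_area @ dz**2
        with np.errstate(invalid="ignore", divide="ignore"):
            out = I**2 / denom
    else:
        occupied = ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dbar = dz.sum(axis=0) / occupied
            out = I / dbar
    return np.where(I > 0, out, np.nan)


def indices_from_surface(surface: DensitySurface, bias_corrected=False) -> AnnualIndices:
    northing, easting = center_of_gravity(surface)
    return AnnualIndices(
        years=surface.years.copy(),
        index=abundance_index(surface),
        northing=northing,
        easting=easting,
        eao=effective_area_occupied(surface),
        bias_corrected=bias_corrected,
    )


def bias_correct_indices(fit: ModelFit, grid_covariates: pd.DataFrame | None = None,
                         n_draws: int = 500, seed: int = 0,
                         stations: pd.DataFrame | None = None) -> AnnualIndices:
    """Retransformation-bias-corrected indices by Laplace-Gaussian simulation.

    Draws the random effects from N(u_hat, H^{-1}) — the Gaussian the Laplace
    approximation places at the inner mode — recomputes I_t, COG and A_t for
    each draw, and reports the draw mean as the corrected value with the draw
    SD as its SE.  With zero random-effect variance the draws collapse on the
    mode and the corrected values equal the plug-in values.  A non-PD
    curvature falls back to the plug-in surface with a warning.

    ``stations`` defaults to nothing needed: the curvature is rebuilt from
    the fitted context stored on the fit's mesh/config; pass the fitted
    station table to recompute it.
    """
    plug = indices_from_surface(predict_density(fit, grid_covariates))
    if stations is None:
        raise ValueError("bias correction needs the fitted station table")
    ctx = LikelihoodContext(stations, fit.mesh, basis=fit.basis,
                            fields_on=fit.config.fields_on,
                            covariate_in_p2=fit.config.covariate_in_p2,
                            range_km=fit.field_params.range_km)
    if ctx.n_u == 0:
        return plug
    params = dict(
        alpha1=fit.alpha1, alpha2=fit.alpha2, gamma1=fit.gamma1, gamma2=fit.gamma2,
        sds={f: getattr(fit.field_params, "sd_" + f) for f in ctx.fields_on},
        range_km=fit.field_params.range_km, cv=fit.gamma_obs_cv,
    )
    u_hat = ctx.u_from_realization(fit.re_modes)
    try:
        _, _, cho, _ = ctx.inner_mode(params, u0=u_hat, tol=1e-8)
        L = np.tril(cho[0]) if cho[1] else np.triu(cho[0]).T
    except np.linalg.LinAlgError:
        warnings.warn("non-PD curvature; bias correction falls back to plug-in")
        return plug
    rng = np.random.default_rng(seed)
    ny = len(fit.years)
    acc = {k: np.zeros((n_draws, ny)) for k in ("index", "northing", "easting", "eao")}
    for it in range(n_draws):
        z = rng.standard_normal(ctx.n_u)
        # u = u_hat + L^{-T} z has covariance (L L^T)^{-1} = H^{-1}
        u = u_hat + solve_triangular(L.T, z, lower=False)
        surf = predict_density(fit, grid_covariates, re=ctx.realization_from_u(u))
        acc["index"][it] = abundance_index(surf)
        n_, e_ = center_of_gravity(surf)
        acc["northing"][it] = n_
        acc["easting"][it] = e_
        acc["eao"][it] = effective_area_occupied(surf)
    return AnnualIndices(
        years=fit.years.copy(),
        index=acc["index"].mean(axis=0),
        northing=acc["northing"].mean(axis=0),
        easting=acc["easting"].mean(axis=0),
        eao=acc["eao"].mean(axis=0),
        se_index=acc["index"].std(axis=0, ddof=1),
        se_northing=acc["northing"].std(axis=0, ddof=1),
        se_easting=acc["easting"].std(axis=0, ddof=1),
        se_eao=acc["eao"].std(axis=0, ddof=1),
        bias_corrected=True,
    )


def annual_index_table(fit: ModelFit, grid_covariates=None, stations=None,
                       bias_correct=True, n_draws=500, seed=0) -> pd.DataFrame:
    """Convenience: per-year CSV-ready table of indices (corrected if requested)."""
    if bias_correct:
        idx = bias_correct_indices(fit, grid_covariates, n_draws=n_draws,
                                   seed=seed, stations=stations)
    else:
        idx = indices_from_surface(predict_density(fit, grid_covariates))
    return idx.to_frame()
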
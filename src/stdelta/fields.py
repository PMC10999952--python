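"""Gaussian random fields at knots with Matérn (nu = 1) correlation.

Two kinds of fields enter each linear predictor: a time-invariant spatial
field omega and a year-specific spatio-temporal field epsilon (independent
across years).  Both live at the mesh knots; stations and grid cells inherit
the value of their nearest knot.

The correlation function is the Matérn with smoothness nu = 1 (the 2-D SPDE
default), parameterised by the distance at which correlation has decayed to
0.1 — the conventional "range" reported for these models.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import brentq
from scipy.special import kv

__all__ = [
    "FieldParams",
    "FieldRealization",
    "matern_correlation",
    "simulate_fields",
    "field_log_density",
]

#: kappa * range such that (kappa d) K1(kappa d) = 0.1; solved once at import.
_KAPPA_RANGE_01 = None


def _matern1(x):
    """(x) K1(x) for x > 0, 1 at x = 0 (Matérn nu=1 correlation in scaled distance)."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    pos = x > 0
    out[pos] = x[pos] * kv(1, x[pos])
    return out


def _kappa_range() -> float:
    """Scaled distance x* with x* K1(x*) = 0.1 (defines the 0.1-correlation range)."""
    global _KAPPA_RANGE_01
    if _KAPPA_RANGE_01 is None:
        _KAPPA_RANGE_01 = brentq(
            lambda x: float(_matern1(np.array([x]))[0]) - 0.1, 1e-6, 50.0
        )
    return _KAPPA_RANGE_01


@dataclass(frozen=True)
class FieldParams:
    """Marginal SDs (log-density units) and shared correlation range of the fields.

    ``range_km`` is the distance at which correlation drops to 0.1.
    A field with SD exactly 0 is switched off (no random effect).
    """

    sd_omega1: float = 0.0
    sd_omega2: float = 0.0
    sd_eps1: float = 0.0
    sd_eps2: float = 0.0
    range_km: float = 150.0

    def __post_init__(self):
        for name in ("sd_omega1", "sd_omega2", "sd_eps1", "sd_eps2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.range_km <= 0:
            raise ValueError("range_km must be > 0")

    def with_(self, **kw) -> "FieldParams":
        return replace(self, **kw)


@dataclass
class FieldRealization:
    """Field values: omega (n_knots,) and epsilon (n_knots, n_years) per predictor."""

    omega1: np.ndarray
    omega2: np.ndarray
    eps1: np.ndarray
    eps2: np.ndarray

    @classmethod
    def zeros(cls, n_knots: int, n_years: int) -> "FieldRealization":
        return cls(
            omega1=np.zeros(n_knots),
            omega2=np.zeros(n_knots),
            eps1=np.zeros((n_knots, n_years)),
            eps2=np.zeros((n_knots, n_years)),
        )

    def to_frame(self, years=None):
        """Long CSV-ready table: knot_id, year, omega1, omega2, eps1, eps2."""
        import pandas as pd

        nk, ny = self.eps1.shape
        years = np.arange(ny) if years is None else np.asarray(years)
        return pd.DataFrame({
            "knot_id": np.repeat(np.arange(nk), ny),
            "year": np.tile(years, nk),
            "omega1": np.repeat(self.omega1, ny),
            "omega2": np.repeat(self.omega2, ny),
            "eps1": self.eps1.ravel(),
            "eps2": self.eps2.ravel(),
        })


def matern_correlation(dist_matrix: np.ndarray, range_km: float, jitter: float = 1e-8):
    """Matérn nu=1 correlation matrix with C(range_km) = 0.1.

    C(d) = (kappa d) K1(kappa d) with kappa chosen so that correlation at
    ``range_km`` equals 0.1; the diagonal is 1 + ``jitter`` for numerical
    positive-definiteness.
    """
    d = np.asarray(dist_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dist_matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("dist_matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    kappa = _kappa_range() / range_km
    corr = _matern1(kappa * d)
    corr[np.eye(len(d), dtype=bool)] = 1.0 + jitter
    return corr


def knot_correlation(knots: np.ndarray, range_km: float) -> np.ndarray:
    """Correlation matrix among knot locations (km coordinates)."""
    diff = knots[:, None, :] - knots[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    d = 0.5 * (d + d.T)
    return matern_correlation(d, range_km)


def simulate_fields(mesh, params: FieldParams, n_years: int, seed) -> FieldRealization:
    """Draw omega ~ MVN(0, sd^2 C) and epsilon_t iid across years.

    Reproducible under ``seed`` (int or numpy Generator).
    """
    rng = np.random.default_rng(seed)
    nk = mesh.n_knots
    corr = knot_correlation(mesh.knots, params.range_km)
    L = cholesky(corr, lower=True)

    def draw(sd, shape):
        if sd == 0:
            return np.zeros((nk,) + shape)
        z = rng.standard_normal((nk,) + shape)
        return sd * np.einsum("ij,j...->i...", L, z)

    return FieldRealization(
        omega1=draw(params.sd_omega1, ()),
        omega2=draw(params.sd_omega2, ()),
        eps1=draw(params.sd_eps1, (n_years,)),
        eps2=draw(params.sd_eps2, (n_years,)),
    )


def _mvn_logpdf(values: np.ndarray, sd: float, cho_corr) -> float:
    """Log density of columns of ``values`` under MVN(0, sd^2 C); columns independent."""
    v = np.atleast_2d(values.T).T  # (nk, ncol)
    nk, ncol = v.shape
    if sd <= 0:
        raise ValueError("sd must be > 0 for a density evaluation")
    alpha = cho_solve(cho_corr, v)
    quad = np.sum(v * alpha) / sd**2
    logdet_corr = 2.0 * np.sum(np.log(np.diag(cho_corr[0])))
    logdet = nk * 2.0 * np.log(sd) + logdet_corr
    return -0.5 * (ncol * nk * np.log(2 * np.pi) + ncol * logdet + quad)


def field_log_density(realization: FieldRealization, params: FieldParams, mesh) -> float:
    """Exact MVN log density of a field realization (active fields only).

    Fields with SD 0 must be identically zero and contribute 0; epsilon
    years contribute independently.
    """
    corr = knot_correlation(mesh.knots, params.range_km)
    cho = cho_factor(corr, lower=True)
    total = 0.0
    for vals, sd, name in (
        (realization.omega1, params.sd_omega1, "omega1"),
        (realization.omega2, params.sd_omega2, "omega2"),
        (realization.eps1, params.sd_eps1, "eps1"),
        (realization.eps2, params.sd_eps2, "eps2"),
    ):
        if sd == 0:
            if np.any(vals != 0):
                raise ValueError(f"{name} has sd=0 but nonzero values")
            continue
        total += _mvn_logpdf(np.asarray(vals, dtype=float), sd, cho)
    return float(total)


def correlation_cholesky(knots: np.ndarray, range_km: float) -> np.ndarray:
    """Lower Cholesky factor of the knot correlation matrix (cached by callers)."""
    return cholesky(knot_correlation(knots, range_km), lower=True)


def correlation_precision(knots: np.ndarray, range_km: float):
    """(precision matrix, log-determinant) of the knot correlation matrix."""
    L = correlation_cholesky(knots, range_km)
    Linv = solve_triangular(L, np.eye(len(L)), lower=True)
    prec = Linv.T @ Linv
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return prec, logdet
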
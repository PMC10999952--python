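"""Synthetic trawl-survey studies with the structure the analysis assumes.

The generator draws a complete study from the forward model: an unbalanced
multi-year station layout on a shelf-scale domain, a temperature field with
warm/cool stanza means plus a smooth spatial gradient, spatial and
spatio-temporal Gaussian random fields at k-means knots, linear predictors
through the Poisson-link, and zero-inflated positively skewed catches from
the delta-gamma observation model.  The known truth (density surface on the
extrapolation grid and the annual indices computed from it) is returned
alongside the data so every downstream stage can be tested for recovery.

Defaults describe a desk-scale late-summer shelf survey: 8 years by 120
stations roughly 55 km apart, encounter probabilities around 0.5-0.9, catch
CV 0.8, field SDs 0.7 (spatial) and 0.5 (spatio-temporal) with a 150 km
correlation range, and a dome-shaped thermal response peaking at 11 °C when
the temperature covariate is switched on.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fields import FieldParams, simulate_fields
from .geo import SpatialMesh, build_mesh, validate_stations
from .indices import AnnualIndices, DensitySurface, indices_from_surface
from .model import poisson_link

__all__ = ["SimScenario", "SurveySimulation", "simulate_survey", "simulate_diet",
           "DEFAULT_PREY_CATEGORIES"]

# survey domain sits at boreal latitudes; northings are km from the Equator
_LAT0_KM = 54.0 * 111.195

DEFAULT_PREY_CATEGORIES = (
    "age0_pollock", "other_fishes", "euphausiids", "calanus", "amphipods",
)

# stanza-conditional expected diet composition (order matches the tuple above):
# warm years dominated by age-0 pollock, cool years by euphausiids/Calanus
_DIET_WARM = np.array([0.50, 0.20, 0.10, 0.10, 0.10])
_DIET_COOL = np.array([0.10, 0.15, 0.40, 0.20, 0.15])


@dataclass(frozen=True)
class SimScenario:
    """The stated world of one synthetic study.

    ``stanzas`` tags each year warm/cool; year intercepts and temperature
    means follow the stanza.  ``covariate_effect`` switches the truth:
    None, 'dome' (quadratic in temperature, peak at ``dome_peak``), or
    'linear' (slope ``linear_gamma1`` on the unit-variance 'prey' covariate).
    """

    n_years: int = 8
    stations_per_year: int | Sequence[int] = 120
    domain_km: tuple = (900.0, 550.0)   # 160 lattice nodes at 55 km spacing
    station_spacing_km: float = 55.0
    n_knots: int = 25
    buffer_km: float = 25.0
    grid_spacing_km: float = 10.0
    field_params: FieldParams = dc_field(
        default_factory=lambda: FieldParams(sd_omega1=0.7, sd_eps1=0.5, range_km=150.0)
    )
    stanzas: Optional[Sequence[str]] = None   # default: warm/cool blocks
    alpha1_warm: float = 2.0
    alpha1_cool: float = 1.0
    alpha1_year_sd: float = 0.3
    alpha2_mean: float = 3.0
    alpha2_year_sd: float = 0.2
    temp_warm_mean: float = 11.5
    temp_cool_mean: float = 9.0
    temp_gradient: float = 2.0     # deg C across the domain diagonal
    temp_noise_sd: float = 0.5     # station-level noise around the smooth field
    covariate_effect: Optional[str] = None   # None | 'dome' | 'linear'
    dome_peak: float = 11.0
    dome_curvature: float = 0.15   # p1 penalty per (deg C)^2 from the peak
    linear_gamma1: float = 0.3
    obs_cv: float = 0.8
    area_swept_km2: float = 0.2
    area_swept_cv: float = 0.15
    diet_contrast: float = 1.0     # 0: warm/cool compositions identical
    diet_concentration: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if min(self.domain_km) <= 0:
            raise ValueError("degenerate domain")
        if self.covariate_effect not in (None, "dome", "linear"):
            raise ValueError(f"unknown covariate_effect {self.covariate_effect!r}")
        if self.stanzas is not None and len(self.stanzas) != self.n_years:
            raise ValueError("stanzas must have one entry per year")

    def with_(self, **kw) -> "SimScenario":
        return replace(self, **kw)

    def year_stanzas(self) -> list:
        if self.stanzas is not None:
            return list(self.stanzas)
        # default regime structure: warm opening, cool middle, warm close
        ny = self.n_years
        n_warm1 = max(ny // 3, 1)
        n_cool = max(ny // 3, 1)
        out = ["warm"] * n_warm1 + ["cool"] * n_cool
        out += ["warm"] * (ny - len(out))
        return out[:ny]


@dataclass
class SurveySimulation:
    """A drawn study: data, mesh, truth surface/indices and truth parameters."""

    stations: pd.DataFrame
    mesh: SpatialMesh
    truth_surface: DensitySurface
    truth_indices: AnnualIndices
    truth: dict
    grid_covariates: Optional[pd.DataFrame] = None


def _station_layout(scenario: SimScenario, rng) -> pd.DataFrame:
    """Jittered lattice of candidate stations with per-year random dropouts."""
    ex, ny_km = scenario.domain_km
    sp = scenario.station_spacing_km
    xs = np.arange(sp / 2, ex, sp)
    ys = np.arange(sp / 2, ny_km, sp) + _LAT0_KM
    gx, gy = np.meshgrid(xs, ys)
    base = np.column_stack([gx.ravel(), gy.ravel()])
    n_base = len(base)
    per_year = scenario.stations_per_year
    if np.isscalar(per_year):
        per_year = [int(per_year)] * scenario.n_years
    rows = []
    for t in range(scenario.n_years):
        m = min(per_year[t], n_base)
        keep = np.sort(rng.choice(n_base, size=m, replace=False))
        jitter = rng.uniform(-sp / 4, sp / 4, size=(m, 2))
        xy = base[keep] + jitter
        for j, (x, y) in zip(keep, xy):
            rows.append({"station_id": f"S{j:04d}", "year_index": t,
                         "easting_km": x, "northing_km": y})
    return pd.DataFrame(rows)


def _temperature(scenario: SimScenario, xy: np.ndarray, year_index: np.ndarray,
                 stanza_mean: np.ndarray, rng=None) -> np.ndarray:
    """Smooth temperature field; station noise added only when rng is given."""
    ex, ny_km = scenario.domain_km
    # warm in the southeast (high easting, low northing), cooling to the northwest
    grad = scenario.temp_gradient * (
        (xy[:, 0] / ex) - ((xy[:, 1] - _LAT0_KM) / ny_km)
    ) / 2.0
    temp = stanza_mean[year_index] + grad
    if rng is not None:
        temp = temp + rng.normal(0.0, scenario.temp_noise_sd, size=len(temp))
    return temp


def _covariate_p1_offset(scenario: SimScenario, temp, prey):
    if scenario.covariate_effect == "dome":
        return -scenario.dome_curvature * (np.asarray(temp) - scenario.dome_peak) ** 2
    if scenario.covariate_effect == "linear":
        return scenario.linear_gamma1 * np.asarray(prey)
    return np.zeros(len(np.atleast_1d(temp)))


def simulate_survey(scenario: SimScenario) -> SurveySimulation:
    """Draw one complete survey study from the forward model.

    Returns the station table (lon/lat back-projected from the plane, area
    swept, catch, temp_20m and prey covariates), the knot mesh, and the truth
    density surface with its annual indices.  Fully deterministic under
    ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    ny = scenario.n_years
    years = 2002 + np.arange(ny)
    stanzas = scenario.year_stanzas()
    is_warm = np.array([s == "warm" for s in stanzas])

    layout = _station_layout(scenario, rng)
    t_i = layout["year_index"].to_numpy()
    xy = layout[["easting_km", "northing_km"]].to_numpy()

    # mesh over the pooled station locations (same construction the fit uses)
    proto = layout.copy()
    proto["year"] = years[t_i]
    mesh = build_mesh(proto, scenario.n_knots, buffer_km=scenario.buffer_km,
                      seed=scenario.seed, grid_spacing_km=scenario.grid_spacing_km)
    k_i = mesh.assign(xy)

    real = simulate_fields(mesh, scenario.field_params, ny, rng)

    alpha1 = np.where(is_warm, scenario.alpha1_warm, scenario.alpha1_cool) \
        + rng.normal(0.0, scenario.alpha1_year_sd, size=ny)
    alpha2 = scenario.alpha2_mean + rng.normal(0.0, scenario.alpha2_year_sd, size=ny)
    stanza_mean = np.where(is_warm, scenario.temp_warm_mean, scenario.temp_cool_mean)

    temp = _temperature(scenario, xy, t_i, stanza_mean, rng=rng)
    # unit-variance prey covariate: smooth knot-level structure plus local noise
    prey_knot = np.sqrt(0.5) * simulate_fields(
        mesh, FieldParams(sd_eps1=1.0, range_km=scenario.field_params.range_km),
        ny, rng,
    ).eps1
    prey = prey_knot[k_i, t_i] + np.sqrt(0.5) * rng.standard_normal(len(t_i))

    p1 = alpha1[t_i] + real.omega1[k_i] + real.eps1[k_i, t_i] \
        + _covariate_p1_offset(scenario, temp, prey)
    p2 = alpha2[t_i] + real.omega2[k_i] + real.eps2[k_i, t_i]

    a = scenario.area_swept_km2 * np.exp(
        rng.normal(0.0, scenario.area_swept_cv, size=len(t_i))
        - scenario.area_swept_cv**2 / 2
    )
    r1, r2 = poisson_link(p1, p2, a)
    enc = rng.random(len(t_i)) < r1
    if scenario.obs_cv > 0:
        shape = 1.0 / scenario.obs_cv**2
        pos = rng.gamma(shape, r2 * scenario.obs_cv**2)
    else:
        pos = r2
    catch = np.where(enc, pos, 0.0)
    if scenario.obs_cv == 0:
        # noiseless limit: expected catch a*exp(p1+p2), no encounter thinning
        catch = a * np.exp(p1 + p2)

    # back-project the plane to lon/lat so the table round-trips through I/O
    lat = xy[:, 1] / 111.195
    lon = xy[:, 0] / (111.195 * np.cos(np.deg2rad(lat))) - 180.0
    stations = pd.DataFrame({
        "station_id": layout["station_id"],
        "year": years[t_i],
        "lon": lon,
        "lat": lat,
        "area_swept": a,
        "catch": catch,
        "temp_20m": temp,
        "prey": prey,
    })
    stations = validate_stations(stations)

    # truth surface on the grid from the same predictors (smooth covariates)
    knot_id = mesh.grid_cells["knot_id"].to_numpy()
    cell_xy = mesh.grid_cells[["x_km", "y_km"]].to_numpy(dtype=float)
    n_cells = len(knot_id)
    cell_t = np.repeat(np.arange(ny), n_cells)
    cell_rep = np.tile(np.arange(n_cells), ny)
    cell_temp = _temperature(scenario, cell_xy[cell_rep], cell_t, stanza_mean)
    cell_prey = prey_knot[knot_id[cell_rep], cell_t]
    cp1 = alpha1[cell_t] + real.omega1[knot_id[cell_rep]] \
        + real.eps1[knot_id[cell_rep], cell_t] \
        + _covariate_p1_offset(scenario, cell_temp, cell_prey)
    cp2 = alpha2[cell_t] + real.omega2[knot_id[cell_rep]] \
        + real.eps2[knot_id[cell_rep], cell_t]
    d = np.exp(cp1 + cp2).reshape(ny, n_cells).T
    truth_surface = DensitySurface(
        cell_xy=cell_xy,
        cell_area=mesh.grid_cells["area_km2"].to_numpy(dtype=float),
        years=years,
        d=d,
    )
    truth_indices = indices_from_surface(truth_surface)

    cov_name = "temp_20m" if scenario.covariate_effect == "dome" else "prey"
    grid_cov = pd.DataFrame({
        "cell_id": cell_rep,
        "year": years[cell_t],
        "value": cell_temp if scenario.covariate_effect == "dome" else cell_prey,
    }) if scenario.covariate_effect else None

    truth = dict(
        years=years, stanzas=stanzas, alpha1=alpha1, alpha2=alpha2,
        field_params=scenario.field_params, fields=real,
        obs_cv=scenario.obs_cv, covariate_effect=scenario.covariate_effect,
        covariate_name=cov_name if scenario.covariate_effect else None,
        dome_peak=scenario.dome_peak, linear_gamma1=scenario.linear_gamma1,
    )
    return SurveySimulation(stations=stations, mesh=mesh,
                            truth_surface=truth_surface,
                            truth_indices=truth_indices, truth=truth,
                            grid_covariates=grid_cov)


def simulate_diet(scenario: SimScenario,
                  categories: Sequence[str] = DEFAULT_PREY_CATEGORIES,
                  stations_per_year: int = 25, seed: Optional[int] = None
                  ) -> pd.DataFrame:
    """Pooled stomach samples whose composition tracks the warm/cool stanza.

    Per station the prey-weight composition is Dirichlet around the stanza's
    expected proportions (age-0 pollock dominating warm years, euphausiids
    and Calanus cool years); ``scenario.diet_contrast`` = 0 removes the
    stanza difference.  Predator weights are lognormal pooled weights.
    """
    if len(categories) == 0:
        raise ValueError("need at least one prey category")
    rng = np.random.default_rng(scenario.seed + 1 if seed is None else seed)
    years = 2002 + np.arange(scenario.n_years)
    stanzas = scenario.year_stanzas()
    ncat = len(categories)
    warm = _resize_props(_DIET_WARM, ncat)
    cool = _resize_props(_DIET_COOL, ncat)
    mean = (warm + cool) / 2.0
    rows = []
    for t, year in enumerate(years):
        base = mean + scenario.diet_contrast * (
            (warm if stanzas[t] == "warm" else cool) - mean
        )
        base = np.maximum(base, 1e-3)
        base = base / base.sum()
        for j in range(stations_per_year):
            n_stomachs = int(rng.integers(5, 31))
            predator_weight = float(n_stomachs * 200.0 * np.exp(rng.normal(0, 0.3)))
            total_prey = predator_weight * rng.uniform(0.005, 0.03)
            props = rng.dirichlet(scenario.diet_concentration * base)
            rec = {
                "station_id": f"D{t:02d}{j:03d}",
                "year": int(year),
                "n_stomachs": n_stomachs,
                "predator_weight": predator_weight,
            }
            for c, p in zip(categories, props):
                rec[c] = total_prey * p
            rows.append(rec)
    return pd.DataFrame(rows)


def _resize_props(base: np.ndarray, ncat: int) -> np.ndarray:
    if ncat == len(base):
        return base.copy()
    if ncat < len(base):
        out = base[:ncat].copy()
    else:
        out = np.concatenate([base, np.full(ncat - len(base), base.min())])
    return out / out.sum()
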
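"""Planar coordinates, knot meshes and covariate gap-filling for survey data.

Survey stations arrive as (lon, lat) records.  All spatial modelling is done
on a simple equirectangular plane: northing is kilometres from the Equator,
easting is kilometres from the 180° meridian scaled by cos(latitude).  This
keeps centre-of-gravity output directly interpretable in km and matches the
reporting convention used for north Pacific trawl surveys.

The spatial support of the random fields is a set of knots placed by k-means
on the pooled station locations; density is predicted on a regular lattice of
grid cells clipped to a buffer around the knots, each cell inheriting the
value of its nearest knot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError, cKDTree
from sklearn.cluster import KMeans

#: km per degree of latitude (spherical Earth, 2*pi*R/360 with R = 6371.0 km
#: rounded to the conventional 111.195 used in survey reporting).
KM_PER_DEGREE = 111.195

REQUIRED_COLUMNS = ("station_id", "year", "lon", "lat", "area_swept", "catch")


def project_coordinates(lon, lat):
    """Project (lon, lat) degrees to (easting_km, northing_km).

    northing_km = 111.195 * lat  (km from the Equator)
    easting_km  = 111.195 * cos(lat) * (lon + 180)  (km from 180°)

    Western-hemisphere longitudes are negative, so the eastern Bering Sea
    (lon ~ -160 to -175) lands at modest positive eastings.

    Parameters
    ----------
    lon, lat : scalar or array-like, degrees.

    Returns
    -------
    (easting_km, northing_km) with the input's shape.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    bad = ~(np.isfinite(lon) & np.isfinite(lat))
    if np.any(bad):
        idx = int(np.argmax(np.atleast_1d(bad)))
        raise ValueError(f"non-finite lon/lat at record {idx}")
    if np.any(lon < -180) or np.any(lon > 180):
        raise ValueError("longitude outside [-180, 180]")
    if np.any(lat <= -90) or np.any(lat >= 90):
        raise ValueError("latitude outside (-90, 90)")
    northing = KM_PER_DEGREE * lat
    easting = KM_PER_DEGREE * np.cos(np.deg2rad(lat)) * (lon + 180.0)
    return easting[()], northing[()]


def validate_stations(stations: pd.DataFrame) -> pd.DataFrame:
    """Validate a station table and add easting_km / northing_km columns.

    Required columns: station_id, year, lon, lat, area_swept, catch.
    Any other column is treated as a covariate (missing values allowed).
    Raises ``ValueError`` on violated invariants, naming the offending record.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in stations.columns]
    if missing:
        raise ValueError(f"station table missing columns: {missing}")
    out = stations.copy()
    if out.empty:
        raise ValueError("empty station table")
    if (out["area_swept"] <= 0).any():
        bad = out.loc[out["area_swept"] <= 0, "station_id"].iloc[0]
        raise ValueError(f"area_swept must be > 0 (station {bad!r})")
    if (out["catch"] < 0).any():
        bad = out.loc[out["catch"] < 0, "station_id"].iloc[0]
        raise ValueError(f"catch must be >= 0 (station {bad!r})")
    dup = out.duplicated(subset=["station_id", "year"])
    if dup.any():
        bad = out.loc[dup, ["station_id", "year"]].iloc[0]
        raise ValueError(
            f"duplicate record for station {bad['station_id']!r} year {bad['year']}"
        )
    e, n = project_coordinates(out["lon"].to_numpy(), out["lat"].to_numpy())
    out["easting_km"] = e
    out["northing_km"] = n
    return out


def read_stations(path) -> pd.DataFrame:
    """Read a station CSV and validate it (empty cells become NaN covariates)."""
    return validate_stations(pd.read_csv(path))


@dataclass
class SpatialMesh:
    """Knot mesh plus extrapolation grid.

    Attributes
    ----------
    knots : (n_knots, 2) array of km coordinates (easting, northing).
    station_to_knot : (n_stations,) index of the nearest knot per station row
        of the table the mesh was built from.
    grid_cells : DataFrame with cell_id, x_km, y_km, area_km2, knot_id.
    buffer_km : clipping radius around knots for the extrapolation grid.
    """

    knots: np.ndarray
    station_to_knot: np.ndarray
    grid_cells: pd.DataFrame
    buffer_km: float
    grid_spacing_km: float = 10.0
    _tree: cKDTree = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        self._tree = cKDTree(self.knots)

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    @property
    def total_area(self) -> float:
        return float(self.grid_cells["area_km2"].sum())

    def assign(self, xy: np.ndarray) -> np.ndarray:
        """Nearest-knot index for (n, 2) km coordinates."""
        return self._tree.query(np.atleast_2d(xy))[1]

    def knots_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "knot_id": np.arange(self.n_knots),
                "x_km": self.knots[:, 0],
                "y_km": self.knots[:, 1],
            }
        )


def build_mesh(
    stations: pd.DataFrame,
    n_knots: int,
    buffer_km: float = 25.0,
    seed: int = 0,
    grid_spacing_km: float = 10.0,
) -> SpatialMesh:
    """Place knots by k-means over pooled station locations and build the grid.

    The extrapolation grid is a regular lattice with spacing
    ``grid_spacing_km`` covering the knot bounding box inflated by
    ``buffer_km``; cells whose centre is farther than ``buffer_km`` from every
    knot are dropped, and each retained cell is assigned to its nearest knot.
    Cell area is the lattice spacing squared.
    """
    if n_knots < 1:
        raise ValueError("n_knots must be >= 1")
    if stations.empty:
        raise ValueError("empty station set")
    if buffer_km <= 0:
        raise ValueError("buffer_km must be > 0")
    xy = stations[["easting_km", "northing_km"]].to_numpy(dtype=float)
    n_distinct = len(np.unique(xy, axis=0))
    if n_knots > n_distinct:
        raise ValueError(
            f"n_knots={n_knots} exceeds {n_distinct} distinct station locations"
        )
    km = KMeans(n_clusters=n_knots, n_init=10, random_state=seed)
    km.fit(xy)
    knots = km.cluster_centers_.copy()
    # deterministic knot ordering regardless of k-means label permutation
    order = np.lexsort((knots[:, 1], knots[:, 0]))
    knots = knots[order]

    tree = cKDTree(knots)
    lo = knots.min(axis=0) - buffer_km
    hi = knots.max(axis=0) + buffer_km
    xs = np.arange(lo[0] + grid_spacing_km / 2, hi[0], grid_spacing_km)
    ys = np.arange(lo[1] + grid_spacing_km / 2, hi[1], grid_spacing_km)
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    dist, knot_id = tree.query(centers)
    keep = dist <= buffer_km
    centers = centers[keep]
    knot_id = knot_id[keep]
    grid = pd.DataFrame(
        {
            "cell_id": np.arange(len(centers)),
            "x_km": centers[:, 0],
            "y_km": centers[:, 1],
            "area_km2": grid_spacing_km**2,
            "knot_id": knot_id,
        }
    )
    station_to_knot = tree.query(xy)[1]
    return SpatialMesh(
        knots=knots,
        station_to_knot=station_to_knot,
        grid_cells=grid,
        buffer_km=buffer_km,
        grid_spacing_km=grid_spacing_km,
    )


def _interpolate_year(xy_obs, values, xy_missing):
    """Linear barycentric interpolation with nearest-neighbour fallback.

    Degenerate (collinear or < 3 point) configurations fall back to 1-D
    linear interpolation along the principal axis of the observed points.
    """
    out = np.full(len(xy_missing), np.nan)
    if len(xy_obs) >= 3:
        try:
            lin = LinearNDInterpolator(xy_obs, values)
            out = lin(xy_missing)
        except QhullError:
            pass
    if np.any(np.isnan(out)) and len(xy_obs) >= 2:
        # collinear / outside hull: project on the principal axis, 1-D linear
        center = xy_obs.mean(axis=0)
        u, s, vt = np.linalg.svd(xy_obs - center, full_matrices=False)
        axis = vt[0]
        t_obs = (xy_obs - center) @ axis
        t_mis = (xy_missing - center) @ axis
        order = np.argsort(t_obs)
        nan = np.isnan(out)
        out[nan] = np.interp(t_mis[nan], t_obs[order], values[order])
    if np.any(np.isnan(out)):
        nn = NearestNDInterpolator(xy_obs, values)
        nan = np.isnan(out)
        out[nan] = nn(xy_missing[nan])
    return out


def fill_missing_covariate(stations: pd.DataFrame, covariate_name: str) -> pd.DataFrame:
    """Fill missing covariate values by within-year spatial interpolation.

    Uses linear barycentric interpolation over the year's observed stations;
    points outside the convex hull (or degenerate configurations) get the
    nearest observed value.  A boolean ``<name>_filled`` column records the
    provenance of every filled value.

    Raises
    ------
    ValueError if the covariate is entirely missing in some year.
    """
    if covariate_name not in stations.columns:
        raise ValueError(f"unknown covariate {covariate_name!r}")
    out = stations.copy()
    flag = np.zeros(len(out), dtype=bool)
    values = out[covariate_name].to_numpy(dtype=float)
    for year, idx in out.groupby("year").indices.items():
        obs = idx[np.isfinite(values[idx])]
        mis = idx[~np.isfinite(values[idx])]
        if len(mis) == 0:
            continue
        if len(obs) == 0:
            raise ValueError(
                f"covariate {covariate_name!r} entirely missing in year {year}"
            )
        xy_obs = out.iloc[obs][["easting_km", "northing_km"]].to_numpy(dtype=float)
        xy_mis = out.iloc[mis][["easting_km", "northing_km"]].to_numpy(dtype=float)
        if len(obs) == 1:
            filled = np.full(len(mis), values[obs[0]])
        else:
            filled = _interpolate_year(xy_obs, values[obs], xy_mis)
        values[mis] = filled
        flag[mis] = True
    out[covariate_name] = values
    out[covariate_name + "_filled"] = flag
    return out
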
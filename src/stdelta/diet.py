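"""Stomach-content index (SCI) and annual diet proportions.

Stomach contents from several fish at a station are pooled; the SCI of a
prey taxon is 10,000 times the pooled prey weight divided by the pooled
predator weight.  Annual summaries average station SCIs per prey category
(unweighted by default) and report each category's share of the summed
category means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "station_sci",
    "annual_diet_summary",
    "water_column_integration",
    "SCI_SCALE",
]

SCI_SCALE = 10_000.0

_META_COLUMNS = ("station_id", "year", "n_stomachs", "predator_weight")


def _prey_columns(records: pd.DataFrame) -> list:
    return [c for c in records.columns if c not in _META_COLUMNS]


def station_sci(records: pd.DataFrame) -> pd.DataFrame:
    """Per-station, per-taxon SCI: 10,000 * prey weight / predator weight.

    ``records`` columns: station_id, year, n_stomachs, predator_weight, then
    one column of pooled prey weight (g) per taxon.
    """
    prey = _prey_columns(records)
    if not prey:
        raise ValueError("no prey-weight columns found")
    pw = records["predator_weight"].to_numpy(dtype=float)
    if np.any(pw <= 0):
        bad = records.loc[pw <= 0, "station_id"].iloc[0]
        raise ValueError(f"predator_weight must be > 0 (station {bad!r})")
    W = records[prey].to_numpy(dtype=float)
    if np.any(W < 0):
        raise ValueError("prey weights must be >= 0")
    out = records[["station_id", "year"]].copy()
    out[prey] = SCI_SCALE * W / pw[:, None]
    return out


def map_categories(sci: pd.DataFrame, category_of: dict | None) -> pd.DataFrame:
    """Sum taxon SCI columns into prey categories (taxon -> category table)."""
    if category_of is None:
        return sci
    prey = _prey_columns(sci)
    unmapped = [t for t in prey if t not in category_of]
    if unmapped:
        raise ValueError(f"taxa without a prey category: {unmapped}")
    out = sci[["station_id", "year"]].copy()
    for cat in dict.fromkeys(category_of.values()):
        cols = [t for t in prey if category_of[t] == cat]
        out[cat] = sci[cols].sum(axis=1)
    return out


def annual_diet_summary(records: pd.DataFrame,
                        category_of: dict | None = None,
                        weight_by_stomachs: bool = False) -> pd.DataFrame:
    """Annual mean SCI and diet proportion per prey category.

    Category SCI is the mean over that year's stations (optionally weighted
    by the number of pooled stomachs); the proportion is the category mean
    divided by the sum of category means, so proportions sum to 1 per year.
    Years whose category means are all zero get NaN proportions.

    Returns a long table: year, category, mean_sci, proportion.
    """
    sci = map_categories(station_sci(records), category_of)
    cats = _prey_columns(sci)
    rows = []
    for year, grp in sci.groupby("year"):
        if weight_by_stomachs:
            w = records.loc[grp.index, "n_stomachs"].to_numpy(dtype=float)
            means = {c: float(np.average(grp[c], weights=w)) for c in cats}
        else:
            means = {c: float(grp[c].mean()) for c in cats}
        total = sum(means.values())
        for c in cats:
            rows.append({
                "year": year,
                "category": c,
                "mean_sci": means[c],
                "proportion": means[c] / total if total > 0 else np.nan,
            })
    return pd.DataFrame(rows)


def water_column_integration(density_per_m3, depth_m):
    """Integrate a volumetric plankton density (# m^-3) over the sampled column.

    Bongo nets fish from 10 m off bottom to the surface, so the areal
    density (# m^-2) is the volumetric density times (depth - 10 m).
    """
    density = np.asarray(density_per_m3, dtype=float)
    depth = np.asarray(depth_m, dtype=float)
    if np.any(depth <= 10):
        raise ValueError("depth_m must exceed the 10 m off-bottom net offset")
    return (density * (depth - 10.0))[()]
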
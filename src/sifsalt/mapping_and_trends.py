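"""Salinity maps, salt-affected/saline area accounting and trend statistics.

Predicted (site, year) classes are rasterized to the native 0.05-degree
grid; salt-affected area counts pixels of class slightly-saline or worse
(EC >= 2 dS/m) and saline area pixels of class moderately-saline or worse
(EC >= 4 dS/m), so saline pixels are a subset of salt-affected pixels by
construction.  Pixel areas use the spherical cosine-of-latitude
approximation, adequate at 0.05 degrees.  Trends are per-site least-squares
slopes of class index against year (Theil-Sen optional), with a dead-band
around zero separating "stable" from a real direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    EARTH_RADIUS_KM,
    InputError,
    NODATA,
    SALINE_MIN_CLASS,
    SALT_AFFECTED_MIN_CLASS,
)

__all__ = [
    "GridMeta",
    "pixel_area_km2",
    "rasterize_classes",
    "predict_classes",
    "predict_map",
    "area_summary",
    "trend_analysis",
    "interannual_variability",
]


@dataclass(frozen=True)
class GridMeta:
    """Geotransform of a north-up lon/lat raster: the grid origin is the
    upper-left corner; ``raster[i, j]`` covers
    ``[lon0 + j*res, lon0 + (j+1)*res) x (lat1 - (i+1)*res, lat1 - i*res]``."""

    lon0: float
    lat1: float  # top latitude
    res: float
    nrows: int
    ncols: int

    def lat_centers(self) -> np.ndarray:
        return self.lat1 - (np.arange(self.nrows) + 0.5) * self.res

    def lon_centers(self) -> np.ndarray:
        return self.lon0 + (np.arange(self.ncols) + 0.5) * self.res


def pixel_area_km2(lat_center, res: float) -> np.ndarray:
    """Spherical pixel area (km^2) at the given center latitude(s):
    ``(R * res_rad)^2 * cos(lat)``."""
    res_rad = np.radians(res)
    return (EARTH_RADIUS_KM * res_rad) ** 2 * np.cos(np.radians(
        np.asarray(lat_center, dtype=float)))


def rasterize_classes(
    lon: np.ndarray,
    lat: np.ndarray,
    classes: np.ndarray,
    *,
    bounds: tuple[float, float, float, float],
    res: float = 0.05,
) -> tuple[np.ndarray, GridMeta]:
    """Grid per-site classes onto a 0.05-degree raster.

    ``bounds = (lon0, lat0, lon1, lat1)``.  Where several sites fall in one
    pixel the highest class wins (conservative for salinization mapping);
    empty pixels are nodata."""
    lon0, lat0, lon1, lat1 = bounds
    ncols = int(np.ceil(round((lon1 - lon0) / res, 6)))
    nrows = int(np.ceil(round((lat1 - lat0) / res, 6)))
    meta = GridMeta(lon0=lon0, lat1=lat1, res=res, nrows=nrows, ncols=ncols)
    raster = np.full((nrows, ncols), NODATA, dtype=np.uint8)
    cols = np.floor((np.asarray(lon) - lon0) / res).astype(int)
    rows = np.floor((lat1 - np.asarray(lat)) / res).astype(int)
    ok = (cols >= 0) & (cols < ncols) & (rows >= 0) & (rows < nrows)
    ok &= np.isfinite(np.asarray(classes, dtype=float))
    cls = np.asarray(classes)[ok].astype(int)
    # highest class wins within a pixel
    order = np.argsort(cls, kind="stable")
    raster[rows[ok][order], cols[ok][order]] = cls[order]
    return raster, meta


def predict_classes(models: dict, sifi_table: pd.DataFrame) -> pd.Series:
    """Predict a salinity class for every row of a SIFI feature table.

    ``models`` maps cell id ``(cell_lon, cell_lat)`` to a fitted
    :class:`~sifsalt.types.RegionModel`; the table needs ``cell_lon,
    cell_lat`` and the model's feature columns.  Raises
    :class:`InputError` listing any cell without a model."""
    cells = list(
        sifi_table[["cell_lon", "cell_lat"]].itertuples(index=False, name=None)
    )
    missing = sorted({c for c in cells if c not in models})
    if missing:
        raise InputError(f"cells without a model: {missing}")
    pred = np.empty(len(sifi_table), dtype=float)
    cell_arr = pd.Series(cells, index=sifi_table.index)
    for cell, idx in cell_arr.groupby(cell_arr).groups.items():
        model = models[cell]
        block = sifi_table.loc[idx, model.feature_set.columns]
        complete = block.notna().all(axis=1)
        vals = np.full(len(block), np.nan)
        if complete.any():
            vals[complete.to_numpy()] = model.predict(
                block[complete].to_numpy(dtype=float))
        pred[sifi_table.index.get_indexer(idx)] = vals
    return pd.Series(pred, index=sifi_table.index, name="predicted_class")


def predict_map(
    models: dict,
    sifi_table: pd.DataFrame,
    year: int,
    *,
    bounds: tuple[float, float, float, float],
    res: float = 0.05,
) -> tuple[np.ndarray, GridMeta]:
    """Classified salinity map for one year (rows with a missing feature
    propagate to nodata pixels)."""
    sub = sifi_table[sifi_table["year"] == year]
    if sub.empty:
        raise InputError(f"no SIFI rows for year {year}")
    pred = predict_classes(models, sub)
    return rasterize_classes(
        sub["lon"].to_numpy(), sub["lat"].to_numpy(), pred.to_numpy(),
        bounds=bounds, res=res,
    )


def area_summary(
    raster: np.ndarray,
    meta: GridMeta,
    region_mask: np.ndarray | None = None,
) -> dict[str, float]:
    """Salt-affected and saline pixel counts and areas (km^2).

    ``region_mask`` (boolean, same shape) restricts the accounting to a
    sub-region; a shape mismatch raises :class:`InputError`."""
    if raster.shape != (meta.nrows, meta.ncols):
        raise InputError("raster does not match its grid metadata")
    if region_mask is None:
        region_mask = np.ones_like(raster, dtype=bool)
    elif region_mask.shape != raster.shape:
        raise InputError("region mask misaligned with raster")
    valid = (raster != NODATA) & region_mask
    area_row = pixel_area_km2(meta.lat_centers(), meta.res)
    area_grid = np.broadcast_to(area_row[:, None], raster.shape)
    salt = valid & (raster >= SALT_AFFECTED_MIN_CLASS)
    saline = valid & (raster >= SALINE_MIN_CLASS)
    return {
        "n_pixels": int(valid.sum()),
        "n_salt_affected_pixels": int(salt.sum()),
        "n_saline_pixels": int(saline.sum()),
        "salt_affected_km2": float(area_grid[salt].sum()),
        "saline_km2": float(area_grid[saline].sum()),
        "total_km2": float(area_grid[valid].sum()),
    }


def trend_analysis(
    site_classes: pd.DataFrame,
    *,
    eps: float = 0.01,
    method: str = "ols",
    min_years: int = 3,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-site salinity trend over years and the regional direction mix.

    ``site_classes`` is a long table ``site_id, year, value`` (class index
    or EC).  The slope is least-squares by default or Theil-Sen with
    ``method="theilsen"``; direction is ``increasing``/``decreasing`` when
    ``|slope| >= eps`` (units per year) and ``stable`` otherwise.  Sites
    with fewer than ``min_years`` years are skipped and counted.

    Returns the per-site table and a summary with the three direction
    fractions (summing to 1 over classified sites) plus counts."""
    if method not in ("ols", "theilsen"):
        raise InputError(f"unknown method {method!r}")
    rows = []
    n_skipped = 0
    for site, grp in site_classes.groupby("site_id", sort=True):
        grp = grp.dropna(subset=["value"])
        yrs = grp["year"].to_numpy(dtype=float)
        vals = grp["value"].to_numpy(dtype=float)
        if len(np.unique(yrs)) < min_years:
            n_skipped += 1
            continue
        if method == "ols":
            slope = float(np.polyfit(yrs, vals, 1)[0])
        else:
            slope = float(stats.theilslopes(vals, yrs).slope)
        if slope >= eps:
            direction = "increasing"
        elif slope <= -eps:
            direction = "decreasing"
        else:
            direction = "stable"
        rows.append({"site_id": site, "slope": slope, "direction": direction,
                     "n_years": int(len(np.unique(yrs)))})
    per_site = pd.DataFrame(rows)
    n = len(per_site)
    summary = {"n_sites": n, "n_skipped": n_skipped}
    for d in ("increasing", "decreasing", "stable"):
        summary[f"frac_{d}"] = (
            float((per_site["direction"] == d).mean()) if n else float("nan")
        )
    return per_site, summary


def interannual_variability(areas: pd.Series) -> tuple[pd.DataFrame, float]:
    """Year-over-year percent change of an area series and its volatility.

    ``areas`` is indexed by year.  Percent change is
    ``(A_t - A_{t-1}) / A_{t-1} * 100``; years following a zero area are
    flagged undefined (NaN).  Volatility is the standard deviation of the
    defined changes."""
    if len(areas) < 2:
        raise InputError("need at least two years")
    areas = areas.sort_index()
    prev = areas.shift(1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = (areas - prev) / prev * 100.0
    pct[prev == 0] = np.nan
    out = pd.DataFrame({"area": areas, "pct_change": pct})
    out["undefined"] = prev.isna() | (prev == 0)
    defined = pct.to_numpy()[1:]
    defined = defined[np.isfinite(defined)]
    vol = float(np.std(defined, ddof=0)) if defined.size else float("nan")
    return out, vol
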
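"""1-degree-cell partition of the study domain and typical/atypical typing.

Each site maps to the 1 x 1 degree cell ``(floor(lon), floor(lat))``
(half-open boundaries).  A cell is *typical* when annual-mean fluorescence
differs significantly (Welch two-sample t-test, two-sided, p < alpha)
between its non-saline samples (class 0, EC < 2 dS/m) and its
salt-affected samples (class >= 1, EC >= 2 dS/m); otherwise — including
when either group is too small to test — it is *atypical* and later served
by a transferred model.  Treating untestable cells as atypical is the
conservative route: they fall back to the transfer pathway rather than
claiming a local signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import InputError, SALT_AFFECTED_MIN_CLASS

__all__ = [
    "assign_cell",
    "classify_cell",
    "classify_cell_anova",
    "classify_cells",
    "partition_summary",
]


def assign_cell(lon, lat, domain: tuple[tuple[float, float],
                                        tuple[float, float]] | None = None):
    """Cell id ``(floor(lon), floor(lat))`` for scalar or array coordinates.

    When ``domain = ((lon0, lon1), (lat0, lat1))`` is given, coordinates
    outside it raise :class:`InputError`."""
    lon_a = np.asarray(lon, dtype=float)
    lat_a = np.asarray(lat, dtype=float)
    if domain is not None:
        (lo0, lo1), (la0, la1) = domain
        if np.any((lon_a < lo0) | (lon_a >= lo1) | (lat_a < la0)
                  | (lat_a >= la1)):
            raise InputError("coordinates outside the configured domain")
    clon = np.floor(lon_a).astype(int)
    clat = np.floor(lat_a).astype(int)
    if np.isscalar(lon):
        return int(clon), int(clat)
    return clon, clat


def classify_cell(values_non: np.ndarray, values_salt: np.ndarray,
                  *, alpha: float = 0.05,
                  min_n: int = 5) -> tuple[float, str]:
    """Welch t-test between non-saline and salt-affected fluorescence.

    Returns ``(p_value, cell_type)``; an untestable cell (either group
    below ``min_n``) is ``(nan, "atypical")``."""
    a = np.asarray(values_non, dtype=float)
    b = np.asarray(values_salt, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < min_n or len(b) < min_n:
        return float("nan"), "atypical"
    _, p = stats.ttest_ind(a, b, equal_var=False)
    return float(p), ("typical" if p < alpha else "atypical")


def classify_cell_anova(values_by_class, *, alpha: float = 0.05,
                        min_n: int = 5) -> tuple[float, str]:
    """Five-group alternative to :func:`classify_cell`: one-way ANOVA of
    fluorescence across all salinity classes instead of the two-group
    Welch contrast.  Classes below ``min_n`` members are ignored; fewer
    than two eligible classes makes the cell atypical with a missing p."""
    groups = [np.asarray(v, dtype=float) for v in values_by_class]
    groups = [g[np.isfinite(g)] for g in groups]
    groups = [g for g in groups if len(g) >= min_n]
    if len(groups) < 2:
        return float("nan"), "atypical"
    _, p = stats.f_oneway(*groups)
    return float(p), ("typical" if p < alpha else "atypical")


def classify_cells(
    samples: pd.DataFrame,
    annual_fluor: pd.DataFrame,
    *,
    alpha: float = 0.05,
    min_n: int = 5,
    test: str = "welch",
    domain=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition samples into cells and type every cell.

    ``samples`` needs ``site_id, lon, lat, year, salinity_class``;
    ``annual_fluor`` is the ``site_id, year, value`` table from
    :func:`sifsalt.sif_index.aggregate_annual`.  Each (site, year) sample is
    paired with that year's annual-mean fluorescence; the non-saline group
    is class 0 and the salt-affected group class >= 1.

    Returns ``(cells, samples_with_cells)`` where ``cells`` has one row per
    occupied cell (``cell_lon, cell_lat, n_samples, n_non, n_salt, p_value,
    cell_type``).
    """
    merged = samples.merge(annual_fluor, on=["site_id", "year"], how="inner")
    if merged.empty:
        raise InputError("no overlap between samples and annual fluorescence")
    clon, clat = assign_cell(merged["lon"].to_numpy(),
                             merged["lat"].to_numpy(), domain=domain)
    merged = merged.assign(cell_lon=clon, cell_lat=clat)

    if test not in ("welch", "anova"):
        raise InputError(f"unknown cell test {test!r}")
    rows = []
    for (cx, cy), grp in merged.groupby(["cell_lon", "cell_lat"], sort=True):
        salt = grp["salinity_class"] >= SALT_AFFECTED_MIN_CLASS
        if test == "welch":
            p, ctype = classify_cell(
                grp.loc[~salt, "value"].to_numpy(),
                grp.loc[salt, "value"].to_numpy(),
                alpha=alpha, min_n=min_n,
            )
        else:
            p, ctype = classify_cell_anova(
                [g["value"].to_numpy()
                 for _, g in grp.groupby("salinity_class")],
                alpha=alpha, min_n=min_n,
            )
        rows.append({
            "cell_lon": cx, "cell_lat": cy, "n_samples": int(len(grp)),
            "n_non": int((~salt).sum()), "n_salt": int(salt.sum()),
            "p_value": p, "cell_type": ctype,
        })
    cells = pd.DataFrame(rows)
    cell_type = cells.set_index(["cell_lon", "cell_lat"])["cell_type"]
    merged["cell_type"] = cell_type.loc[
        pd.MultiIndex.from_arrays([merged["cell_lon"], merged["cell_lat"]])
    ].to_numpy()
    return cells, merged


def partition_summary(cells: pd.DataFrame) -> dict[str, int]:
    """Counts of typical/atypical cells and their member samples."""
    typical = cells["cell_type"] == "typical"
    return {
        "n_typical_cells": int(typical.sum()),
        "n_atypical_cells": int((~typical).sum()),
        "n_typical_samples": int(cells.loc[typical, "n_samples"].sum()),
        "n_atypical_samples": int(cells.loc[~typical, "n_samples"].sum()),
    }
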
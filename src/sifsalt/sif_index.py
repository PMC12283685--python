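"""Standardized solar-induced chlorophyll fluorescence index (SIFI).

The SIFI adapts the standardized-precipitation-index (SPI) recipe to
fluorescence.  For a chosen anchor month and a time scale ``i`` in 1..12,
the fluorescence record of a site is reduced to one accumulation per year
(the mean of the ``i`` consecutive monthly means ending at the anchor
month), a two-parameter Gamma distribution

    f(x; alpha, beta) = x**(alpha-1) * exp(-x/beta) / (Gamma(alpha) * beta**alpha)

is fitted to those accumulations by maximum likelihood, and each year's
accumulation x is mapped to a standard-normal score

    SIFI_i = Phi^{-1}( G(x; alpha, beta) )

where G is the Gamma CDF and Phi^{-1} the standard-normal quantile.  The
index is therefore dimensionless, approximately N(0, 1) over a site's own
history, and negative in years when fluorescence is anomalously low —
e.g. under salinity stress.

The Gamma MLE is solved from the sufficient statistic
``s = log(mean(x)) - mean(log(x))`` via Newton iteration on
``log(alpha) - digamma(alpha) = s`` (Thom's approximation as the starting
point), with ``beta = mean(x) / alpha``.  The fitted CDF value is clamped
to ``[1/(2n), 1 - 1/(2n)]`` before the normal quantile so extreme ranks
cannot map to infinity.

By default the Gamma is fitted per site x scale x anchor month across
years, following the SPI convention of standardizing against each
location's own climatology; a pooled fit across sites is available via
``pooled=True``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .types import (
    DegenerateFitError,
    GammaParams,
    InputError,
    InsufficientDataError,
)

__all__ = [
    "aggregate_monthly",
    "aggregate_annual",
    "accumulate",
    "fit_gamma_mle",
    "gamma_cdf",
    "sifi_transform",
    "compute_sifi",
    "sifi1_by_anchor",
    "FLUOR_FLOOR",
]

#: positive floor applied to fluorescence before Gamma fitting (the Gamma
#: requires strictly positive support; CSIF-like products can contain
#: non-positive values).
FLUOR_FLOOR = 1e-6

_MIN_FIT_N = 8


# ---------------------------------------------------------------------------
# temporal aggregation
# ---------------------------------------------------------------------------

def aggregate_monthly(fluor: pd.DataFrame) -> pd.DataFrame:
    """Mean fluorescence per site, calendar year and month.

    ``fluor`` is a long table ``site_id, date, value``; returns
    ``site_id, year, month, value``.  Months with no observation are simply
    absent (treated as missing downstream)."""
    if fluor.empty:
        raise InputError("empty fluorescence table")
    dates = pd.DatetimeIndex(fluor["date"])
    out = (
        fluor.assign(year=dates.year, month=dates.month)
        .groupby(["site_id", "year", "month"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    return out


def aggregate_annual(fluor: pd.DataFrame) -> pd.DataFrame:
    """Mean fluorescence per site and calendar year (``site_id, year,
    value``), used to align fluorescence with annually sampled salinity."""
    if fluor.empty:
        raise InputError("empty fluorescence table")
    dates = pd.DatetimeIndex(fluor["date"])
    return (
        fluor.assign(year=dates.year)
        .groupby(["site_id", "year"], sort=True)["value"]
        .mean()
        .reset_index()
    )


def _monthly_panel(monthly: pd.DataFrame
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pivot the long monthly table to a (site, consecutive-month) matrix.

    Returns (site_ids, first_year, matrix) where matrix column
    ``(year - first_year) * 12 + month - 1`` holds that month's mean and
    missing months are NaN."""
    y0, y1 = int(monthly["year"].min()), int(monthly["year"].max())
    months = (monthly["year"].to_numpy() - y0) * 12 + monthly["month"].to_numpy() - 1
    sites = np.unique(monthly["site_id"].to_numpy())
    mat = np.full((sites.size, (y1 - y0 + 1) * 12), np.nan)
    rows = np.searchsorted(sites, monthly["site_id"].to_numpy())
    mat[rows, months] = monthly["value"].to_numpy()
    return sites, np.array([y0]), mat


def accumulate(monthly: pd.DataFrame, scale: int,
               anchor_month: int) -> pd.DataFrame:
    """Per-year accumulation: mean of ``scale`` consecutive monthly values
    ending at the anchor month (crossing into the previous calendar year
    when ``scale > anchor_month``).

    Returns ``site_id, year, value`` with NaN where the window is
    incomplete (including the leading year(s) that lack history).  The mean
    rather than the sum is used; the two differ by a constant factor and
    standardize identically."""
    if not 1 <= scale <= 12:
        raise InputError(f"scale must lie in 1..12, got {scale}")
    if not 1 <= anchor_month <= 12:
        raise InputError(f"anchor_month must lie in 1..12, got {anchor_month}")
    sites, (y0,), mat = _monthly_panel(monthly)
    n_years = mat.shape[1] // 12
    years = y0 + np.arange(n_years)
    vals = np.full((sites.size, n_years), np.nan)
    for j, y in enumerate(years):
        end = j * 12 + anchor_month  # exclusive
        startcol = end - scale
        if startcol < 0:
            continue
        window = mat[:, startcol:end]
        vals[:, j] = window.mean(axis=1)  # NaN if any member missing
    return pd.DataFrame({
        "site_id": np.repeat(sites, n_years),
        "year": np.tile(years, sites.size),
        "value": vals.ravel(),
    })


# ---------------------------------------------------------------------------
# Gamma fitting
# ---------------------------------------------------------------------------

def _alpha_from_s(s: np.ndarray, n_iter: int = 25) -> np.ndarray:
    """Solve log(alpha) - digamma(alpha) = s by Newton iteration,
    vectorized; s must be positive."""
    s = np.asarray(s, dtype=float)
    # Thom (1958) approximation as starting point
    alpha = (1.0 + np.sqrt(1.0 + 4.0 * s / 3.0)) / (4.0 * s)
    for _ in range(n_iter):
        f = np.log(alpha) - special.digamma(alpha) - s
        fp = 1.0 / alpha - special.polygamma(1, alpha)
        step = f / fp
        alpha = np.clip(alpha - step, alpha * 0.1, alpha * 10.0)
    return alpha


def fit_gamma_mle(sample, min_n: int = _MIN_FIT_N) -> GammaParams:
    """Maximum-likelihood fit of a two-parameter Gamma distribution.

    Raises :class:`InputError` for non-positive values (callers must
    preprocess, e.g. clip to :data:`FLUOR_FLOOR`),
    :class:`InsufficientDataError` below ``min_n`` observations and
    :class:`DegenerateFitError` for zero-variance samples."""
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_n:
        raise InsufficientDataError(
            f"need at least {min_n} observations, got {x.size}"
        )
    if np.any(x <= 0):
        raise InputError("gamma fitting requires strictly positive values")
    if np.ptp(x) == 0:
        raise DegenerateFitError("sample has zero variance")
    s = float(np.log(x.mean()) - np.mean(np.log(x)))
    if s <= 0:
        raise DegenerateFitError("degenerate log-moment statistic")
    alpha = float(_alpha_from_s(np.array([s]))[0])
    return GammaParams(alpha=alpha, beta=float(x.mean() / alpha), n=int(x.size))


def gamma_cdf(x, params: GammaParams):
    """Gamma cumulative distribution G(x; alpha, beta) for x >= 0."""
    arr = np.asarray(x, dtype=float)
    if arr.size and np.nanmin(arr) < 0:
        raise InputError("gamma CDF is defined for x >= 0")
    out = stats.gamma.cdf(arr, a=params.alpha, scale=params.beta)
    return float(out) if np.isscalar(x) else out


def sifi_transform(x, params: GammaParams):
    """Standardized index value Phi^{-1}(G(x)) with the CDF clamped to
    ``[1/(2n), 1 - 1/(2n)]`` so extreme ranks stay finite."""
    g = gamma_cdf(x, params)
    lo = 1.0 / (2.0 * params.n)
    out = stats.norm.ppf(np.clip(g, lo, 1.0 - lo))
    return float(out) if np.isscalar(x) else out


# ---------------------------------------------------------------------------
# SIFI computation
# ---------------------------------------------------------------------------

def _fit_rows(vals: np.ndarray, min_years: int
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Gamma MLE over a (site, year) matrix with NaN missing.

    Returns (alpha, beta, n) per row; rows with fewer than ``min_years``
    finite values, non-positive values or zero variance get NaN."""
    finite = np.isfinite(vals)
    n = finite.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, np.nansum(np.where(finite, vals, 0.0), axis=1)
                        / np.maximum(n, 1), np.nan)
        logs = np.where(finite & (vals > 0), np.log(np.where(vals > 0, vals, 1.0)),
                        0.0)
        meanlog = logs.sum(axis=1) / np.maximum(n, 1)
        s = np.log(mean) - meanlog
    bad = ((n < min_years)
           | np.any(finite & (vals <= 0), axis=1)
           | ~np.isfinite(s) | (s <= 0))
    alpha = np.full(vals.shape[0], np.nan)
    ok = ~bad
    if ok.any():
        alpha[ok] = _alpha_from_s(s[ok])
    beta = mean / alpha
    return alpha, beta, n


def compute_sifi(
    monthly: pd.DataFrame,
    anchor_month: int = 12,
    *,
    scales=range(1, 13),
    min_years: int = 8,
    pooled: bool = False,
) -> pd.DataFrame:
    """SIFI at every requested time scale for every site and year.

    For each scale the accumulation series ending at ``anchor_month`` is
    built across years, a Gamma is fitted (per site by default; one pooled
    fit across all sites with ``pooled=True``) and each year's value is
    transformed to its standard-normal score.  Sites or years without a
    valid fit/window get NaN for that scale rather than failing globally.

    Returns a wide table ``site_id, year, anchor_month, sifi_1..sifi_12``.
    """
    if not 1 <= anchor_month <= 12:
        raise InputError(f"anchor_month must lie in 1..12, got {anchor_month}")
    out = None
    for scale in scales:
        acc = accumulate(monthly, scale, anchor_month)
        sites = np.unique(acc["site_id"].to_numpy())
        years = np.unique(acc["year"].to_numpy())
        vals = acc["value"].to_numpy().reshape(sites.size, years.size)
        vals = np.where(np.isfinite(vals),
                        np.maximum(vals, FLUOR_FLOOR), np.nan)
        sifi = np.full_like(vals, np.nan)
        if pooled:
            flat = vals[np.isfinite(vals)]
            if flat.size >= min_years:
                params = fit_gamma_mle(flat, min_n=min_years)
                m = np.isfinite(vals)
                sifi[m] = sifi_transform(vals[m], params)
        else:
            alpha, beta, n = _fit_rows(vals, min_years)
            ok = np.isfinite(alpha)
            if ok.any():
                with np.errstate(invalid="ignore"):
                    g = stats.gamma.cdf(vals[ok], a=alpha[ok, None],
                                        scale=beta[ok, None])
                lo = 1.0 / (2.0 * n[ok, None].astype(float))
                sub = np.where(np.isfinite(vals[ok]),
                               stats.norm.ppf(np.clip(g, lo, 1.0 - lo)),
                               np.nan)
                sifi[ok] = sub
        col = pd.DataFrame({
            "site_id": np.repeat(sites, years.size),
            "year": np.tile(years, sites.size),
            f"sifi_{scale}": sifi.ravel(),
        })
        out = col if out is None else out.merge(col, on=["site_id", "year"],
                                                how="outer")
    if out is None:
        raise InputError("no scales requested")
    out.insert(2, "anchor_month", anchor_month)
    return out


def sifi1_by_anchor(monthly: pd.DataFrame, *, min_years: int = 8,
                    pooled: bool = False) -> pd.DataFrame:
    """One-month SIFI anchored at each calendar month, as a long table
    ``site_id, year, month, value`` — the default input of the monthly
    sensitivity analysis."""
    frames = []
    for m in range(1, 13):
        w = compute_sifi(monthly, anchor_month=m, scales=[1],
                         min_years=min_years, pooled=pooled)
        frames.append(pd.DataFrame({
            "site_id": w["site_id"], "year": w["year"], "month": m,
            "value": w["sifi_1"],
        }))
    return pd.concat(frames, ignore_index=True)
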
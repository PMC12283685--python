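"""Sample screening and salinity-sensitivity testing.

Isolates soil salinity as the dominant fluorescence driver by (a) dropping
sites whose land-cover class changed during the study period and (b)
testing, per stratum (calendar month x land-cover group, or any grouping
the caller supplies), whether fluorescence differs significantly across the
five EC-based salinity classes.

The multi-group comparison is a one-way ANOVA omnibus followed by Tukey HSD
pairwise contrasts; a nonparametric alternative (Kruskal-Wallis omnibus
with Holm-corrected pairwise Mann-Whitney tests) is available because
fluorescence distributions are right-skewed.
"""

from __future__ import annotations

import itertools
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    EC_BREAKS,
    InputError,
    SensitivityResult,
)

__all__ = [
    "ec_to_class",
    "filter_stable_landuse",
    "multigroup_test",
    "monthly_sensitivity",
]


def ec_to_class(ec):
    """Classify electrical conductivity (dS/m) into the five salinity
    classes 0..4 (non, slightly, moderately, highly, extremely saline).

    Intervals are half-open: class k covers ``[break[k-1], break[k])`` with
    the top class unbounded.  Accepts scalars or arrays; EC must be
    strictly positive.
    """
    arr = np.asarray(ec, dtype=float)
    if arr.size and np.nanmin(arr) <= 0:
        raise InputError("EC must be strictly positive (dS/m)")
    out = np.digitize(arr, EC_BREAKS)
    return int(out) if np.isscalar(ec) else out


def filter_stable_landuse(
    samples: pd.DataFrame,
    landuse: pd.DataFrame,
    years: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Retain samples whose site kept a single land-cover id over the span.

    ``samples`` needs a ``site_id`` column; ``landuse`` needs ``site_id,
    year, lc_id``.  Sites without land-cover coverage of the full span are
    dropped (reported separately from changed sites).  Returns the retained
    samples plus a report ``{n_input, n_retained, n_changed_sites,
    n_uncovered_sites, n_dropped}``.
    """
    if years is not None:
        lu = landuse[(landuse["year"] >= years[0])
                     & (landuse["year"] <= years[1])]
        span = years[1] - years[0] + 1
    else:
        lu = landuse
        span = landuse["year"].nunique()

    per_site = lu.groupby("site_id")["lc_id"].agg(["nunique", "count"])
    stable = set(per_site.index[(per_site["nunique"] == 1)
                                & (per_site["count"] >= span)])
    covered = set(per_site.index[per_site["count"] >= span])
    sample_sites = samples["site_id"]
    keep = sample_sites.isin(stable)
    uncovered = set(sample_sites.unique()) - covered
    changed = covered - stable

    retained = samples[keep].copy()
    report = {
        "n_input": int(len(samples)),
        "n_retained": int(len(retained)),
        "n_changed_sites": int(len(changed & set(sample_sites.unique()))),
        "n_uncovered_sites": int(len(uncovered)),
        "n_dropped": int(len(samples) - len(retained)),
    }
    return retained, report


def _holm_pairwise(groups: Mapping[int, np.ndarray]) -> pd.DataFrame:
    keys = sorted(groups)
    rows = []
    for a, b in itertools.combinations(keys, 2):
        stat, p = stats.mannwhitneyu(groups[a], groups[b],
                                     alternative="two-sided")
        rows.append((a, b, stat, p))
    df = pd.DataFrame(rows, columns=["class_a", "class_b", "statistic", "p_raw"])
    from statsmodels.stats.multitest import multipletests
    df["p_adj"] = multipletests(df["p_raw"], method="holm")[1]
    return df


def multigroup_test(
    values: np.ndarray,
    classes: np.ndarray,
    *,
    stratum=None,
    alpha: float = 0.05,
    min_n: int = 5,
    method: str = "anova",
) -> SensitivityResult:
    """Test whether fluorescence differs across salinity classes.

    Groups with fewer than ``min_n`` members are ignored; with fewer than
    two eligible groups the stratum is flagged not-testable (neither
    sensitive nor insensitive).  ``method="anova"`` runs a one-way ANOVA
    omnibus with Tukey HSD pairwise contrasts; ``method="kruskal"`` the
    nonparametric alternative.
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    if values.shape != classes.shape:
        raise InputError("values and classes must align")
    ok = np.isfinite(values)
    values, classes = values[ok], classes[ok]

    groups = {int(c): values[classes == c] for c in np.unique(classes)}
    sizes = {c: len(v) for c, v in groups.items()}
    eligible = {c: v for c, v in groups.items() if len(v) >= min_n}
    if len(eligible) < 2:
        return SensitivityResult(
            stratum=stratum, statistic=float("nan"), p_value=float("nan"),
            significant=False, alpha=alpha, group_sizes=sizes, testable=False,
        )

    arrays = [eligible[c] for c in sorted(eligible)]
    if method == "anova":
        stat, p = stats.f_oneway(*arrays)
        tk = stats.tukey_hsd(*arrays)
        keys = sorted(eligible)
        pairs = [
            (keys[i], keys[j], tk.statistic[i, j], tk.pvalue[i, j])
            for i in range(len(keys)) for j in range(i + 1, len(keys))
        ]
        pairwise = pd.DataFrame(
            pairs, columns=["class_a", "class_b", "statistic", "p_adj"]
        )
    elif method == "kruskal":
        stat, p = stats.kruskal(*arrays)
        pairwise = _holm_pairwise(eligible)
    else:
        raise InputError(f"unknown method {method!r}")

    return SensitivityResult(
        stratum=stratum, statistic=float(stat), p_value=float(p),
        significant=bool(p < alpha), alpha=alpha, group_sizes=sizes,
        testable=True, pairwise=pairwise,
    )


def monthly_sensitivity(
    monthly_values: pd.DataFrame,
    samples: pd.DataFrame,
    *,
    strata: str | None = None,
    alpha: float = 0.05,
    min_n: int = 5,
    method: str = "anova",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-month salinity sensitivity and the most sensitive month per stratum.

    ``monthly_values`` is a long table ``site_id, year, month, value`` —
    either raw monthly-mean fluorescence or one-month SIFI anchored at each
    month (:func:`sifsalt.sif_index.sifi1_by_anchor`); the choice is the
    caller's.  ``samples`` must carry ``site_id, year, salinity_class`` and,
    when ``strata`` names a column, that column (e.g. a land-cover group or
    cell id).

    For each stratum and each calendar month the month's values, joined to
    the same-year salinity class of the site, are run through
    :func:`multigroup_test`.  The most sensitive month of a stratum is the
    one with the smallest omnibus p-value (ties broken toward the smallest
    month index); strata with no testable month get a missing value.
    """
    key_cols = ["site_id", "year", "salinity_class"]
    if strata is not None:
        key_cols.append(strata)
    joined = monthly_values.merge(samples[key_cols], on=["site_id", "year"],
                                  how="inner")
    if joined.empty:
        raise InputError("no overlap between monthly values and samples")

    strat_values = joined[strata].unique() if strata is not None else [None]
    rows = []
    for s in strat_values:
        sub = joined if s is None else joined[joined[strata] == s]
        for month in range(1, 13):
            block = sub[sub["month"] == month]
            res = multigroup_test(
                block["value"].to_numpy(), block["salinity_class"].to_numpy(),
                stratum=(s, month), alpha=alpha, min_n=min_n, method=method,
            )
            rows.append({
                "stratum": s, "month": month, "statistic": res.statistic,
                "p_value": res.p_value, "significant": res.significant,
                "testable": res.testable,
                "n": int(sum(res.group_sizes.values())),
            })
    table = pd.DataFrame(rows)

    best_rows = []
    for s, sub in table.groupby("stratum", dropna=False, sort=False):
        testable = sub[sub["testable"]]
        if testable.empty:
            best_rows.append({"stratum": s, "most_sensitive_month": np.nan,
                              "p_value": np.nan})
        else:
            # stable argmin: smallest p, ties toward the earliest month
            best = testable.sort_values(["p_value", "month"]).iloc[0]
            best_rows.append({"stratum": s,
                              "most_sensitive_month": int(best["month"]),
                              "p_value": float(best["p_value"])})
    return table, pd.DataFrame(best_rows)
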
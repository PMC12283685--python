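"""Per-region random-forest salinity classification.

Typical cells (where fluorescence carries a detectable salinity signal)
get native random-forest classifiers mapping the 12-scale SIFI vector of a
(site, year) to its five-class salinity label.  The SIFI feature subset
(2-10 of the 12 scales) and the forest hyperparameters (number of trees,
maximum depth, feature-sampling fraction) are chosen by stratified k-fold
cross-validated search; depth and feature limits act as capacity
regularization.  Atypical cells are served by the best typical-cell model,
optionally adapted by refitting on a weighted union of source rows and
whatever labelled rows the target cell has ("weighted-refit" transfer).

Class labels are integers 0..4 (non .. extremely saline) throughout.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import KFold, ParameterGrid, StratifiedKFold

from .types import (
    ClassificationReport,
    FeatureSet,
    InputError,
    N_CLASSES,
    RegionModel,
)

__all__ = [
    "DEFAULT_GRID",
    "build_feature_table",
    "cv_accuracy",
    "search_hyperparameters",
    "select_feature_combination",
    "train_region_model",
    "transfer_to_atypical",
    "evaluate",
    "importance_profile",
    "aggregate_importances",
]

#: Exhaustive hyperparameter grid for the cross-validated search.
DEFAULT_GRID: dict[str, list] = {
    "n_estimators": [100, 300],
    "max_depth": [4, 8, 16, None],
    "max_features": ["sqrt", 0.5],
}

SIFI_COLUMNS = [f"sifi_{s}" for s in range(1, 13)]


def build_feature_table(sifi: pd.DataFrame,
                        samples: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Join SIFI vectors to same-year salinity labels.

    One row per (site, year) present in both tables, carrying the 12
    ``sifi_*`` columns, the ``salinity_class`` label and any extra sample
    columns (coordinates, cell ids, land-cover).  Rows with a missing SIFI
    scale are dropped; returns ``(table, n_dropped)``."""
    keep = [c for c in samples.columns if c not in sifi.columns
            or c in ("site_id", "year")]
    merged = sifi.merge(samples[keep], on=["site_id", "year"], how="inner")
    if merged.empty:
        raise InputError("no overlapping (site, year) between SIFI and samples")
    complete = merged[SIFI_COLUMNS].notna().all(axis=1)
    return merged[complete].reset_index(drop=True), int((~complete).sum())


# ---------------------------------------------------------------------------
# cross-validation and search
# ---------------------------------------------------------------------------

def _make_forest(params: Mapping, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(random_state=seed, n_jobs=1, **params)


def _folds(y: np.ndarray, k: int, seed: int):
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            "a class has fewer members than folds; stratification relaxed",
            stacklevel=3,
        )
        return KFold(n_splits=k, shuffle=True, random_state=seed)
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)


def cv_accuracy(X: np.ndarray, y: np.ndarray, params: Mapping,
                k_folds: int = 5, seed: int = 0) -> float:
    """Mean stratified k-fold accuracy of a forest with ``params``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    cv = _folds(y, k_folds, seed)
    accs = []
    for tr, te in cv.split(X, y):
        est = _make_forest(params, seed)
        est.fit(X[tr], y[tr])
        accs.append(float(np.mean(est.predict(X[te]) == y[te])))
    return float(np.mean(accs))


def _depth_key(d) -> float:
    return np.inf if d is None else float(d)


def search_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    grid: Mapping[str, list] | None = None,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[dict, float]:
    """Exhaustive grid search by stratified k-fold CV accuracy.

    Ties are broken toward parsimony — fewer trees, then shallower depth,
    then first-listed — so equal-scoring configurations resolve
    deterministically.  Raises :class:`InputError` on single-class data."""
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise InputError("hyperparameter search needs at least two classes")
    if k_folds < 2:
        raise InputError("k_folds must be >= 2")
    grid = dict(grid) if grid is not None else DEFAULT_GRID
    candidates = list(ParameterGrid(grid))
    scored = []
    for order, params in enumerate(candidates):
        acc = cv_accuracy(X, y, params, k_folds=k_folds, seed=seed)
        scored.append((
            -acc,
            params.get("n_estimators", 0),
            _depth_key(params.get("max_depth")),
            order,
            params,
        ))
    scored.sort(key=lambda t: t[:4])
    best = scored[0]
    return dict(best[4]), -best[0]


def select_feature_combination(
    X: np.ndarray,
    y: np.ndarray,
    *,
    sizes: Iterable[int] = range(2, 11),
    strategy: str = "nested",
    anchor_month: int = 12,
    params: Mapping | None = None,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[FeatureSet, pd.DataFrame]:
    """Choose the SIFI time-scale subset (size 2..10) used as model input.

    ``X`` must have 12 columns ordered by scale.  Strategy ``"nested"``
    ranks scales by impurity importance from a full-feature fit and
    evaluates only the nested prefixes of each requested size;
    ``"exhaustive"`` evaluates every subset of the requested sizes.  Both
    return the subset with the best CV accuracy, ties broken toward the
    smaller subset (then lexicographically earlier scales).

    Returns the winning :class:`FeatureSet` and a table of every evaluated
    candidate with its CV accuracy."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 12:
        raise InputError("X must have 12 columns (scales 1..12)")
    sizes = sorted(set(int(s) for s in sizes))
    if not sizes or sizes[0] < 2 or sizes[-1] > 10:
        raise InputError("subset sizes must lie in 2..10")
    params = dict(params) if params is not None else {
        "n_estimators": 200, "max_features": "sqrt"
    }

    if strategy == "nested":
        full = _make_forest(params, seed)
        full.fit(X, y)
        imp = full.feature_importances_
        # rank scales by importance, ties toward the smaller scale index
        ranked = sorted(range(12), key=lambda j: (-imp[j], j))
        candidates = [tuple(sorted(s + 1 for s in ranked[:k])) for k in sizes]
    elif strategy == "exhaustive":
        candidates = [
            combo
            for k in sizes
            for combo in itertools.combinations(range(1, 13), k)
        ]
    else:
        raise InputError(f"unknown strategy {strategy!r}")

    rows = []
    for combo in candidates:
        cols = [s - 1 for s in combo]
        acc = cv_accuracy(X[:, cols], y, params, k_folds=k_folds, seed=seed)
        rows.append({"scales": combo, "size": len(combo), "cv_accuracy": acc})
    table = pd.DataFrame(rows)
    best = min(rows, key=lambda r: (-r["cv_accuracy"], r["size"], r["scales"]))
    return FeatureSet(scales=best["scales"], anchor_month=anchor_month), table


# ---------------------------------------------------------------------------
# training, transfer, evaluation
# ---------------------------------------------------------------------------

def train_region_model(
    cell_id,
    table: pd.DataFrame,
    feature_set: FeatureSet,
    hyperparameters: Mapping,
    *,
    seed: int = 0,
    k_folds: int = 5,
    provenance: str = "native",
    with_cv: bool = True,
) -> RegionModel:
    """Fit one cell's forest on its labelled rows.

    ``with_cv=False`` skips the k-fold CV-accuracy estimate (recorded as
    NaN) when the model is not a transfer-source candidate.  A single-class
    cell yields a flagged degenerate model (a constant predictor) that is
    excluded from transfer-source candidates."""
    X = table[feature_set.columns].to_numpy(dtype=float)
    y = table["salinity_class"].to_numpy(dtype=int)
    if len(y) == 0:
        raise InputError(f"cell {cell_id} has no labelled rows")
    classes = np.unique(y)
    if classes.size < 2:
        return RegionModel(
            cell_id=cell_id, feature_set=feature_set,
            hyperparameters=dict(hyperparameters), cv_accuracy=float("nan"),
            provenance=provenance, seed=seed, degenerate=True,
            constant_class=int(classes[0]), train_X=X, train_y=y,
        )
    if with_cv:
        k = max(min(k_folds, int(np.bincount(y).max()), len(y)), 2)
        acc = cv_accuracy(X, y, hyperparameters, k_folds=k, seed=seed)
    else:
        acc = float("nan")
    est = _make_forest(hyperparameters, seed)
    est.fit(X, y)
    return RegionModel(
        cell_id=cell_id, feature_set=feature_set,
        hyperparameters=dict(hyperparameters), cv_accuracy=acc,
        provenance=provenance, seed=seed, estimator=est,
        train_X=X, train_y=y,
    )


def transfer_to_atypical(
    source_models: Sequence[RegionModel],
    target_cell,
    target_table: pd.DataFrame | None = None,
    *,
    target_weight: float = 2.0,
    seed: int = 0,
) -> RegionModel:
    """Adapt the best typical-cell model to an atypical cell.

    The source is the non-degenerate native model with the highest CV
    accuracy.  With labelled target rows available, the source's feature
    set and hyperparameters are refitted on a weighted union of source and
    target rows in which the target carries ``target_weight`` times the
    source's influence.  The weighting is realized by resampling — the
    source sample is subsampled to ``n_target / target_weight`` rows —
    rather than by nominal sample weights, because deep axis-aligned
    forests respond to training-row density, not weight: leaves populated
    only by source rows predict source-style regardless of how heavily the
    target rows are weighted elsewhere.  Without any target labels the
    source model is reused unchanged and flagged unadapted."""
    eligible = [m for m in source_models
                if not m.degenerate and np.isfinite(m.cv_accuracy)]
    if not eligible:
        raise InputError("no non-degenerate source models available")
    source = max(eligible, key=lambda m: m.cv_accuracy)

    if target_table is None or len(target_table) == 0:
        return RegionModel(
            cell_id=target_cell, feature_set=source.feature_set,
            hyperparameters=dict(source.hyperparameters),
            cv_accuracy=source.cv_accuracy, provenance="transferred",
            seed=source.seed, estimator=source.estimator, adapted=False,
            train_X=source.train_X, train_y=source.train_y,
        )

    Xt = target_table[source.feature_set.columns].to_numpy(dtype=float)
    yt = target_table["salinity_class"].to_numpy(dtype=int)
    n_src = len(source.train_y)
    n_keep = int(min(n_src, max(1, round(len(yt) / float(target_weight)))))
    rng = np.random.default_rng([seed, 13])
    keep = rng.choice(n_src, n_keep, replace=False)
    X = np.vstack([source.train_X[keep], Xt])
    y = np.concatenate([source.train_y[keep], yt])
    est = _make_forest(source.hyperparameters, seed)
    est.fit(X, y)
    return RegionModel(
        cell_id=target_cell, feature_set=source.feature_set,
        hyperparameters=dict(source.hyperparameters),
        cv_accuracy=source.cv_accuracy, provenance="transferred",
        seed=seed, estimator=est, adapted=True, train_X=X, train_y=y,
    )


def evaluate(model: RegionModel, table: pd.DataFrame) -> ClassificationReport:
    """Five-class confusion matrix and per-class metrics on held-out rows."""
    if len(table) == 0:
        raise InputError("empty held-out table")
    y_true = table["salinity_class"].to_numpy(dtype=int)
    y_pred = model.predict(table[model.feature_set.columns].to_numpy(float))
    labels = list(range(N_CLASSES))
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    empty = tuple(
        c for c in labels
        if cm[c, :].sum() == 0 and cm[:, c].sum() == 0
    )
    return ClassificationReport(
        confusion=cm, precision=prec, recall=rec, f1=f1,
        accuracy=float(np.trace(cm) / cm.sum()), n=int(cm.sum()),
        empty_classes=empty,
    )


# ---------------------------------------------------------------------------
# feature importance
# ---------------------------------------------------------------------------

def importance_profile(
    model: RegionModel,
    table: pd.DataFrame | None = None,
    *,
    method: str = "permutation",
    n_repeats: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Normalized importance of the 12 SIFI scales for one model.

    ``method="permutation"`` (default; needs an evaluation ``table``)
    measures the accuracy drop when one feature is shuffled;
    ``method="impurity"`` uses the forest's built-in importances.  Values
    for scales outside the model's feature set are 0; the profile is
    clipped at 0 and normalized to sum to 1."""
    if model.degenerate or model.estimator is None:
        raise InputError("cannot profile a degenerate or unfitted model")
    if method == "permutation":
        if table is None or len(table) == 0:
            raise InputError("permutation importance needs evaluation rows")
        X = table[model.feature_set.columns].to_numpy(dtype=float)
        y = table["salinity_class"].to_numpy(dtype=int)
        res = permutation_importance(
            model.estimator, X, y, n_repeats=n_repeats, random_state=seed,
            scoring="accuracy",
        )
        raw = res.importances_mean
    elif method == "impurity":
        raw = model.estimator.feature_importances_
    else:
        raise InputError(f"unknown method {method!r}")

    profile = np.zeros(12)
    for value, scale in zip(raw, model.feature_set.scales):
        profile[scale - 1] = max(float(value), 0.0)
    total = profile.sum()
    if total <= 0:  # no feature helps: spread uniformly over used scales
        used = [s - 1 for s in model.feature_set.scales]
        profile[used] = 1.0 / len(used)
    else:
        profile /= total
    return profile


def aggregate_importances(profiles: Mapping, ) -> pd.DataFrame:
    """Average importance profiles by stratum.

    ``profiles`` maps a stratum label (anchor month, land-cover group, ...)
    to a list of 12-vector profiles; returns one row per stratum with
    columns ``sifi_1..sifi_12`` (each row sums to 1)."""
    rows = {}
    for label, plist in profiles.items():
        arr = np.mean(np.asarray(list(plist), dtype=float), axis=0)
        rows[label] = arr / arr.sum()
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=SIFI_COLUMNS)
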
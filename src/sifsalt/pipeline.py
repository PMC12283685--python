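"""End-to-end orchestration: simulate -> SIFI -> screen -> partition ->
train -> transfer -> predict -> areas & trends.

This is glue over the stage modules, used by the command-line interface
and by the reproduction script.  Stage defaults favour a single-CPU run
of the reference scene (2,000 sites x 21 years): the feature-subset
selection and hyperparameter search are run once on the pooled
typical-cell rows (sub-sampled to at most ``search_rows`` rows) and the
chosen configuration is then fitted separately per cell; per-cell searches
remain available through the stage functions directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from . import mapping_and_trends as mt
from . import region_partition as rp
from . import salinity_model as sm
from .sensitivity_screen import filter_stable_landuse, monthly_sensitivity
from .sif_index import (
    aggregate_annual,
    aggregate_monthly,
    compute_sifi,
    sifi1_by_anchor,
)
from .synthetic_data import Scene, SceneConfig, generate_scene
from .types import LC_GROUPS, FeatureSet, InputError

__all__ = [
    "PipelineResult",
    "run_pipeline",
    "native_benchmark",
    "transfer_benchmark",
]

#: reduced grid used for the pipeline's pooled hyperparameter search
PIPELINE_GRID: dict[str, list] = {
    "n_estimators": [200],
    "max_depth": [8, None],
    "max_features": ["sqrt"],
}


@dataclass
class PipelineResult:
    cfg: SceneConfig
    scene: Scene
    screen_report: dict[str, int]
    sensitivity: pd.DataFrame
    most_sensitive_month: pd.DataFrame
    cells: pd.DataFrame
    partition: dict[str, int]
    sifi: pd.DataFrame
    feature_set: FeatureSet
    hyperparameters: dict[str, Any]
    models: dict[tuple[int, int], Any]
    native_cv_accuracies: dict[tuple[int, int], float]
    median_native_cv_accuracy: float
    feature_table: pd.DataFrame
    predictions: pd.DataFrame
    areas: pd.DataFrame
    trend_sites: pd.DataFrame
    trend_summary: dict[str, float]
    map_year: int
    class_map: np.ndarray
    map_meta: mt.GridMeta


def run_pipeline(
    cfg: SceneConfig,
    *,
    anchor_month: int = 12,
    alpha: float = 0.05,
    k_folds: int = 3,
    search_rows: int = 6000,
    feature_sizes=range(2, 11),
    target_weight: float = 2.0,
    map_year: int | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Run the full analysis on one synthetic scene."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng([seed, 77])
    scene = generate_scene(cfg)

    # -- screening: land-use stability filter -------------------------------
    retained, screen_report = filter_stable_landuse(
        scene.samples, scene.landuse, years=cfg.years
    )
    retained = retained.assign(
        lc_group=retained["lc_id"].map(LC_GROUPS)
    )

    # -- temporal aggregation and the standardized index --------------------
    monthly = aggregate_monthly(scene.fluor)
    annual = aggregate_annual(scene.fluor)
    sifi = compute_sifi(monthly, anchor_month=anchor_month)

    # -- per-month sensitivity by land-cover group --------------------------
    sens, best_month = monthly_sensitivity(
        sifi1_by_anchor(monthly), retained.rename(
            columns={"ec_dsm": "ec"}),
        strata="lc_group", alpha=alpha,
    )

    # -- 1-degree partition --------------------------------------------------
    cells, samples_cells = rp.classify_cells(retained, annual, alpha=alpha)
    partition = rp.partition_summary(cells)

    # -- feature table -------------------------------------------------------
    table, _ = sm.build_feature_table(sifi, samples_cells)
    typical_cells = set(
        cells.loc[cells["cell_type"] == "typical",
                  ["cell_lon", "cell_lat"]].itertuples(index=False, name=None)
    )
    atypical_cells = set(
        cells.loc[cells["cell_type"] == "atypical",
                  ["cell_lon", "cell_lat"]].itertuples(index=False, name=None)
    )
    cell_of = list(table[["cell_lon", "cell_lat"]]
                   .itertuples(index=False, name=None))
    is_typical_row = np.array([c in typical_cells for c in cell_of])
    typical_table = table[is_typical_row]
    if typical_table.empty:
        raise InputError("no typical cells: cannot train native models")

    # -- pooled feature selection + hyperparameter search -------------------
    pool = typical_table
    if len(pool) > search_rows:
        pool = pool.sample(search_rows, random_state=int(rng.integers(2**31)))
    Xp = pool[sm.SIFI_COLUMNS].to_numpy(dtype=float)
    yp = pool["salinity_class"].to_numpy(dtype=int)
    feature_set, _ = sm.select_feature_combination(
        Xp, yp, sizes=feature_sizes, strategy="nested",
        anchor_month=anchor_month, k_folds=k_folds, seed=seed,
    )
    params, _ = sm.search_hyperparameters(
        Xp[:, [s - 1 for s in feature_set.scales]], yp,
        grid=PIPELINE_GRID, k_folds=k_folds, seed=seed,
    )

    # -- native models in typical cells -------------------------------------
    models: dict[tuple[int, int], Any] = {}
    native_cv: dict[tuple[int, int], float] = {}
    for cell in sorted(typical_cells):
        rows = typical_table[
            (typical_table["cell_lon"] == cell[0])
            & (typical_table["cell_lat"] == cell[1])
        ]
        if rows.empty:
            continue
        m = sm.train_region_model(cell, rows, feature_set, params,
                                  seed=seed, k_folds=k_folds)
        models[cell] = m
        if np.isfinite(m.cv_accuracy):
            native_cv[cell] = m.cv_accuracy

    # -- transfer to atypical cells ------------------------------------------
    sources = [m for m in models.values() if not m.degenerate]
    for cell in sorted(atypical_cells):
        rows = table[(table["cell_lon"] == cell[0])
                     & (table["cell_lat"] == cell[1])]
        models[cell] = sm.transfer_to_atypical(
            sources, cell, rows if len(rows) else None,
            target_weight=target_weight, seed=seed,
        )

    # -- prediction, maps, areas, trends -------------------------------------
    covered = table[[c in models for c in cell_of]].copy()
    covered["predicted_class"] = mt.predict_classes(models, covered)
    bounds = (cfg.lon_range[0], cfg.lat_range[0],
              cfg.lon_range[1], cfg.lat_range[1])
    map_year = cfg.years[1] if map_year is None else map_year
    class_map, meta = mt.predict_map(models, covered, map_year, bounds=bounds)

    area_rows = []
    for year, grp in covered.groupby("year"):
        raster, m = mt.rasterize_classes(
            grp["lon"].to_numpy(), grp["lat"].to_numpy(),
            grp["predicted_class"].to_numpy(), bounds=bounds,
        )
        area_rows.append({"year": int(year), **mt.area_summary(raster, m)})
    areas = pd.DataFrame(area_rows).set_index("year")

    trend_input = pd.DataFrame({
        "site_id": covered["site_id"],
        "year": covered["year"],
        "value": covered["predicted_class"],
    })
    trend_sites, trend_summary = mt.trend_analysis(trend_input)

    return PipelineResult(
        cfg=cfg, scene=scene, screen_report=screen_report,
        sensitivity=sens, most_sensitive_month=best_month,
        cells=cells, partition=partition, sifi=sifi,
        feature_set=feature_set, hyperparameters=params, models=models,
        native_cv_accuracies=native_cv,
        median_native_cv_accuracy=float(np.median(list(native_cv.values())))
        if native_cv else float("nan"),
        feature_table=table, predictions=covered, areas=areas,
        trend_sites=trend_sites, trend_summary=trend_summary,
        map_year=map_year, class_map=class_map, map_meta=meta,
    )


# ---------------------------------------------------------------------------
# reference benchmarks
# ---------------------------------------------------------------------------

#: forest configuration used by the reference benchmarks
BENCHMARK_PARAMS: dict[str, Any] = {
    "n_estimators": 300, "max_depth": None, "max_features": "sqrt",
}


def _scene_feature_table(cfg: SceneConfig,
                         anchor_month: int = 12) -> pd.DataFrame:
    from .salinity_model import build_feature_table

    scene = generate_scene(cfg)
    sifi = compute_sifi(aggregate_monthly(scene.fluor),
                        anchor_month=anchor_month)
    table, _ = build_feature_table(sifi, scene.samples)
    return table


def native_benchmark(seed: int, *, n_sites: int = 500,
                     test_frac: float = 0.25) -> float:
    """Held-out accuracy of a native model on the typical training scenario.

    Generates the all-sensitive benchmark scene, computes SIFI, splits the
    labelled rows (stratified), fits the reference forest on the training
    part and returns accuracy on the held-out part."""
    from sklearn.model_selection import train_test_split

    from . import salinity_model as sm
    from .synthetic_data import typical_training_scenario
    from .types import FeatureSet

    table = _scene_feature_table(typical_training_scenario(seed=seed,
                                                           n_sites=n_sites))
    train, test = train_test_split(
        table, test_size=test_frac, random_state=seed,
        stratify=table["salinity_class"],
    )
    fs = FeatureSet(scales=tuple(range(1, 13)))
    model = sm.train_region_model("benchmark", train, fs, BENCHMARK_PARAMS,
                                  seed=seed, with_cv=False)
    return sm.evaluate(model, test).accuracy


def transfer_benchmark(seed: int, *, n_target_labels: int = 50
                       ) -> tuple[float, float]:
    """(unadapted, adapted) held-out accuracy on the shifted-target scenario.

    The source model is trained on the full typical scene; ``n_target_labels``
    rows of the saltier target scene are available for weighted-refit
    adaptation and the remainder is the evaluation set."""
    from . import salinity_model as sm
    from .synthetic_data import shifted_transfer_scenario
    from .types import FeatureSet

    src_cfg, tgt_cfg = shifted_transfer_scenario(seed=seed)
    src_table = _scene_feature_table(src_cfg)
    tgt_table = _scene_feature_table(tgt_cfg)
    fs = FeatureSet(scales=tuple(range(1, 13)))
    source = sm.train_region_model("source", src_table, fs, BENCHMARK_PARAMS,
                                   seed=seed, k_folds=2)
    rng = np.random.default_rng([seed, 5])
    idx = rng.permutation(len(tgt_table))
    labelled = tgt_table.iloc[idx[:n_target_labels]]
    heldout = tgt_table.iloc[idx[n_target_labels:]]
    unadapted = sm.transfer_to_atypical([source], "target", None, seed=seed)
    adapted = sm.transfer_to_atypical([source], "target", labelled, seed=seed)
    return (sm.evaluate(unadapted, heldout).accuracy,
            sm.evaluate(adapted, heldout).accuracy)
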
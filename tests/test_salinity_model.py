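"""Feature tables, CV search, subset selection, per-cell forests,
transfer adaptation, evaluation metrics and importances."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import sifsalt as ss
from sifsalt import salinity_model as sm
from sifsalt.types import FeatureSet, InputError

HP_FAST = {"n_estimators": 50, "max_features": "sqrt"}


def toy_table(n_rows=120, informative=(1, 12), n_classes=5, noise=0.3,
              seed=0):
    """Feature table whose label is decodable only from the given scales."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, n_classes, n_rows)
    X = rng.normal(0, 1, (n_rows, 12))
    for s in informative:
        X[:, s - 1] = -y + rng.normal(0, noise, n_rows)
    df = pd.DataFrame(X, columns=sm.SIFI_COLUMNS)
    df["salinity_class"] = y
    return df


class TestBuildFeatureTable:
    def test_full_coverage_keeps_all_rows(self, small_sifi, small_scene):
        samples = small_scene.samples.head(100)
        table, dropped = ss.build_feature_table(small_sifi, samples)
        assert len(table) == 100 and dropped == 0
        assert all(c in table.columns for c in sm.SIFI_COLUMNS)

    def test_missing_year_row_dropped_and_counted(self, small_sifi,
                                                  small_scene):
        samples = small_scene.samples.head(10).copy()
        samples.loc[samples.index[0], "year"] = 1990  # no SIFI for that year
        table, dropped = ss.build_feature_table(small_sifi, samples)
        assert len(table) == 9
        # the vanished row is an inner-join miss, not a NaN drop
        assert dropped == 0

    def test_labels_equal_generator_truth(self, small_table, small_scene):
        truth = small_scene.truth.samples.set_index(["site_id", "year"])
        got = small_table.set_index(["site_id", "year"])["salinity_class"]
        expect = truth.loc[got.index, "salinity_class"]
        np.testing.assert_array_equal(got.to_numpy(), expect.to_numpy())

    def test_no_overlap_rejected(self, small_sifi):
        samples = pd.DataFrame({"site_id": [999], "year": [1900],
                                "salinity_class": [0]})
        with pytest.raises(InputError):
            ss.build_feature_table(small_sifi, samples)


class TestHyperparameterSearch:
    def test_single_point_grid_returns_plain_cv_accuracy(self):
        df = toy_table(seed=1)
        X = df[sm.SIFI_COLUMNS].to_numpy()
        y = df["salinity_class"].to_numpy()
        grid = {"n_estimators": [50], "max_features": ["sqrt"]}
        params, acc = ss.search_hyperparameters(X, y, grid=grid, k_folds=3,
                                                seed=0)
        assert params == {"n_estimators": 50, "max_features": "sqrt"}
        assert acc == pytest.approx(
            ss.cv_accuracy(X, y, params, k_folds=3, seed=0))

    def test_separable_data_reaches_high_accuracy(self):
        df = toy_table(n_rows=300, noise=0.05, seed=2)
        params, acc = ss.search_hyperparameters(
            df[sm.SIFI_COLUMNS].to_numpy(), df["salinity_class"].to_numpy(),
            grid={"n_estimators": [100], "max_features": ["sqrt"]},
            k_folds=3, seed=0)
        assert acc >= 0.95

    def test_permuted_labels_score_at_chance(self):
        rng = np.random.default_rng(3)
        df = toy_table(n_rows=400, noise=0.05, seed=3)
        y = df["salinity_class"].to_numpy().copy()
        rng.shuffle(y)
        _, acc = ss.search_hyperparameters(
            df[sm.SIFI_COLUMNS].to_numpy(), y,
            grid={"n_estimators": [100], "max_features": ["sqrt"]},
            k_folds=5, seed=0)
        assert 0.12 <= acc <= 0.28

    def test_parsimony_tie_break(self):
        # constant features make every configuration score identically
        X = np.zeros((60, 12))
        y = np.repeat(np.arange(3), 20)
        params, _ = ss.search_hyperparameters(
            X, y, grid={"n_estimators": [300, 100],
                        "max_depth": [16, 4, None]}, k_folds=3, seed=0)
        assert params["n_estimators"] == 100
        assert params["max_depth"] == 4

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            ss.search_hyperparameters(np.zeros((20, 12)), np.zeros(20))


class TestFeatureSelection:
    def test_exhaustive_matches_bruteforce_enumeration(self):
        df = toy_table(n_rows=60, informative=(3, 7), noise=0.2, seed=4)
        X = df[sm.SIFI_COLUMNS].to_numpy()
        y = df["salinity_class"].to_numpy()
        fs, table = ss.select_feature_combination(
            X, y, sizes=[2], strategy="exhaustive", params=HP_FAST,
            k_folds=3, seed=0)
        # independent brute force over all C(12,2) pairs with the same CV
        best_combo, best_acc = None, -1.0
        for combo in itertools.combinations(range(1, 13), 2):
            acc = ss.cv_accuracy(X[:, [c - 1 for c in combo]], y, HP_FAST,
                                 k_folds=3, seed=0)
            if acc > best_acc:
                best_combo, best_acc = combo, acc
        assert fs.scales == best_combo
        assert len(table) == 66

    def test_nested_recovers_planted_scales(self):
        df = toy_table(n_rows=250, informative=(1, 12), noise=0.2, seed=5)
        fs, _ = ss.select_feature_combination(
            df[sm.SIFI_COLUMNS].to_numpy(), df["salinity_class"].to_numpy(),
            strategy="nested", params=HP_FAST, k_folds=3, seed=0)
        assert {1, 12} <= set(fs.scales)

    def test_identical_features_tie_toward_smallest_size(self):
        rng = np.random.default_rng(6)
        col = rng.normal(0, 1, 90)
        X = np.tile(col[:, None], (1, 12))  # all 12 features identical
        y = (col > 0).astype(int) + (col > 1)
        fs, _ = ss.select_feature_combination(X, y, strategy="nested",
                                              params=HP_FAST, k_folds=3,
                                              seed=0)
        assert len(fs.scales) == 2

    def test_invalid_sizes_rejected(self):
        df = toy_table(seed=7)
        with pytest.raises(InputError):
            ss.select_feature_combination(
                df[sm.SIFI_COLUMNS].to_numpy(),
                df["salinity_class"].to_numpy(), sizes=[1])


class TestTrainAndTransfer:
    def test_same_seed_refit_identical_predictions(self):
        df = toy_table(seed=8)
        fs = FeatureSet(scales=tuple(range(1, 13)))
        m1 = ss.train_region_model("c", df, fs, HP_FAST, seed=5, with_cv=False)
        m2 = ss.train_region_model("c", df, fs, HP_FAST, seed=5, with_cv=False)
        X = df[fs.columns].to_numpy()
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_depth_limit_restricts_capacity(self):
        df = toy_table(n_rows=400, noise=1.2, seed=9)
        fs = FeatureSet(scales=tuple(range(1, 13)))
        deep = ss.train_region_model("c", df, fs, HP_FAST, seed=0,
                                     with_cv=False)
        shallow = ss.train_region_model(
            "c", df, fs, {**HP_FAST, "max_depth": 1}, seed=0, with_cv=False)
        X = df[fs.columns].to_numpy()
        y = df["salinity_class"].to_numpy()
        assert (shallow.predict(X) == y).mean() < (deep.predict(X) == y).mean()

    def test_single_class_cell_degenerate_and_excluded(self):
        df = toy_table(seed=10)
        df["salinity_class"] = 2
        fs = FeatureSet(scales=(1, 12))
        m = ss.train_region_model("c", df, fs, HP_FAST, seed=0)
        assert m.degenerate and m.constant_class == 2
        assert (m.predict(df[fs.columns].to_numpy()) == 2).all()
        with pytest.raises(InputError):
            ss.transfer_to_atypical([m], "t", None)

    def test_source_selection_by_cv_accuracy(self):
        df = toy_table(seed=11)
        fs = FeatureSet(scales=(1, 12))
        good = ss.train_region_model("a", df, fs, HP_FAST, seed=0,
                                     with_cv=False)
        bad = ss.train_region_model("b", df, fs, HP_FAST, seed=0,
                                    with_cv=False)
        good.cv_accuracy, bad.cv_accuracy = 0.9, 0.7
        chosen = ss.transfer_to_atypical([bad, good], "t", None)
        assert chosen.estimator is good.estimator
        assert chosen.provenance == "transferred" and chosen.adapted is False

    def test_no_shift_adaptation_harmless(self):
        # identical source/target distribution with a generous label set:
        # adapted and unadapted accuracies agree within Monte-Carlo noise
        df_src = toy_table(n_rows=600, noise=0.4, seed=12)
        df_tgt = toy_table(n_rows=600, noise=0.4, seed=13)
        fs = FeatureSet(scales=tuple(range(1, 13)))
        src = ss.train_region_model("s", df_src, fs,
                                    {"n_estimators": 100}, seed=0,
                                    with_cv=False)
        src.cv_accuracy = 1.0
        lab, te = df_tgt.iloc[:300], df_tgt.iloc[300:]
        una = ss.transfer_to_atypical([src], "t", None, seed=0)
        ada = ss.transfer_to_atypical([src], "t", lab, seed=0)
        acc_u = ss.evaluate(una, te).accuracy
        acc_a = ss.evaluate(ada, te).accuracy
        assert abs(acc_u - acc_a) <= 0.06

    def test_adaptation_gains_under_label_shift(self):
        # target labels are remapped: adaptation must beat plain reuse
        df_src = toy_table(n_rows=400, noise=0.2, seed=14)
        df_tgt = toy_table(n_rows=400, noise=0.2, seed=15)
        df_tgt["salinity_class"] = (df_tgt["salinity_class"] + 1) % 5
        fs = FeatureSet(scales=tuple(range(1, 13)))
        src = ss.train_region_model("s", df_src, fs, {"n_estimators": 100},
                                    seed=0, with_cv=False)
        src.cv_accuracy = 1.0
        lab, te = df_tgt.iloc[:50], df_tgt.iloc[50:]
        acc_u = ss.evaluate(ss.transfer_to_atypical([src], "t", None, seed=0),
                            te).accuracy
        acc_a = ss.evaluate(ss.transfer_to_atypical([src], "t", lab, seed=0),
                            te).accuracy
        assert acc_a > acc_u + 0.2


class TestEvaluate:
    def test_perfect_predictions(self):
        df = toy_table(n_rows=100, noise=0.0, seed=16)
        fs = FeatureSet(scales=(1, 12))
        m = ss.train_region_model("c", df, fs, {"n_estimators": 100}, seed=0,
                                  with_cv=False)
        rep = ss.evaluate(m, df)  # training rows: sanity of the identities
        assert rep.accuracy == 1.0
        assert np.all(rep.f1[np.unique(df["salinity_class"])] == 1.0)
        assert rep.confusion.sum() == rep.n == 100

    def test_metrics_match_hand_computed_matrix(self):
        # construct predictions realizing a known 5x5 confusion matrix
        cm = np.array([
            [50, 3, 0, 0, 0],
            [4, 30, 5, 0, 0],
            [0, 6, 20, 2, 0],
            [0, 0, 3, 10, 1],
            [0, 0, 0, 2, 5],
        ])
        y_true = np.repeat(np.arange(5), cm.sum(axis=1))
        y_pred = np.concatenate([np.repeat(np.arange(5), row) for row in cm])

        class _Fake:
            feature_set = FeatureSet(scales=(1,))
            degenerate = False

            def predict(self, X):
                return y_pred

        fake = ss.RegionModel(
            cell_id="c", feature_set=FeatureSet(scales=(1,)),
            hyperparameters={}, cv_accuracy=1.0, provenance="native",
            seed=0, estimator=_Fake(),
        )
        table = pd.DataFrame({"sifi_1": np.zeros(len(y_true)),
                              "salinity_class": y_true})
        rep = ss.evaluate(fake, table)
        np.testing.assert_array_equal(rep.confusion, cm)
        # hand-computed identities
        for c in range(5):
            col, row = cm[:, c].sum(), cm[c, :].sum()
            prec = cm[c, c] / col if col else 0.0
            rec = cm[c, c] / row if row else 0.0
            assert rep.precision[c] == pytest.approx(prec)
            assert rep.recall[c] == pytest.approx(rec)
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert rep.f1[c] == pytest.approx(f1)
        assert rep.accuracy == pytest.approx(np.trace(cm) / cm.sum())

    def test_constant_predictor_on_balanced_labels(self):
        df = toy_table(n_rows=200, seed=17)
        df["salinity_class"] = np.tile(np.arange(5), 40)
        fs = FeatureSet(scales=(1,))
        const = ss.RegionModel(
            cell_id="c", feature_set=fs, hyperparameters={}, cv_accuracy=0.2,
            provenance="native", seed=0, degenerate=True, constant_class=0,
        )
        rep = ss.evaluate(const, df)
        assert rep.accuracy == pytest.approx(0.2)

    def test_empty_heldout_rejected(self):
        fs = FeatureSet(scales=(1,))
        m = ss.RegionModel(cell_id="c", feature_set=fs, hyperparameters={},
                           cv_accuracy=0.5, provenance="native", seed=0,
                           degenerate=True, constant_class=0)
        with pytest.raises(InputError):
            ss.evaluate(m, pd.DataFrame(columns=["sifi_1", "salinity_class"]))


class TestImportance:
    def test_planted_scale_dominates(self):
        df = toy_table(n_rows=300, informative=(5,), noise=0.2, seed=18)
        fs = FeatureSet(scales=tuple(range(1, 13)))
        m = ss.train_region_model("c", df, fs, {"n_estimators": 100}, seed=0,
                                  with_cv=False)
        for method in ("permutation", "impurity"):
            prof = ss.importance_profile(m, df, method=method, seed=0)
            assert prof.argmax() == 4  # scale 5
            assert prof.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unused_scales_have_zero_importance(self):
        df = toy_table(n_rows=150, informative=(2, 3), seed=19)
        fs = FeatureSet(scales=(2, 3))
        m = ss.train_region_model("c", df, fs, HP_FAST, seed=0, with_cv=False)
        prof = ss.importance_profile(m, df, method="impurity")
        assert prof[[0] + list(range(3, 12))].sum() == 0.0

    def test_aggregation_normalizes_per_stratum(self):
        profiles = {
            "april": [np.full(12, 1 / 12), np.eye(12)[0]],
            "july": [np.eye(12)[11]],
        }
        agg = ss.aggregate_importances(profiles)
        assert np.allclose(agg.sum(axis=1), 1.0)
        assert agg.loc["july", "sifi_12"] == 1.0

    def test_rare_class_recall_degrades_first(self):
        # qualitative imbalance pattern: scarce top classes lose recall
        rng = np.random.default_rng(20)
        df = toy_table(n_rows=2000, informative=(1, 12), noise=0.6, seed=20)
        y = df["salinity_class"].to_numpy()
        keep = np.ones(len(df), bool)
        for rare in (3, 4):
            idx = np.flatnonzero(y == rare)
            keep[rng.choice(idx, int(len(idx) * 0.95), replace=False)] = False
        df = df[keep]
        # refresh features for the new labels
        fs = FeatureSet(scales=tuple(range(1, 13)))
        tr = df.iloc[: int(len(df) * 0.7)]
        te = df.iloc[int(len(df) * 0.7):]
        m = ss.train_region_model("c", tr, fs, {"n_estimators": 200}, seed=0,
                                  with_cv=False)
        rep = ss.evaluate(m, te)
        assert rep.recall[[0, 1]].mean() > rep.recall[[3, 4]].mean()
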
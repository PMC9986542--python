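"""SMOTE oversampling, repeated stratified CV and confusion aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import ConvexHull, Delaunay

from flavimetry.classify import (
    CVPlan,
    FeatureTable,
    aggregate_confusion,
    macro_f_score,
    model_zoo_evaluate,
    repeated_stratified_cv,
    smote_augment,
)


def toy_table(n_per_class=40, seed=0, separation=6.0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i, label in enumerate(["A", "B"]):
        X.append(rng.normal(i * separation, 1.0, size=(n_per_class, 3)))
        y += [label] * n_per_class
    X = np.vstack(X)
    return FeatureTable(X, np.array(y), np.arange(len(y)).astype(str))


class TestSMOTE:
    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array(["a"] * 10 + ["b"] * 10)
        Xb, yb = smote_augment(X, y, rng=rng)
        np.testing.assert_array_equal(Xb, X)
        np.testing.assert_array_equal(yb, y)

    def test_minority_count_arithmetic(self, rng):
        """A 13-member minority against a 94-member majority gains 81 rows."""
        X = rng.normal(size=(107, 3))
        y = np.array(["CTL"] * 13 + ["HGG"] * 94)
        Xb, yb = smote_augment(X, y, rng=rng)
        assert (yb == "CTL").sum() == 94
        assert len(Xb) == 188
        # original rows preserved verbatim
        np.testing.assert_array_equal(Xb[:107], X)

    def test_synthetic_points_inside_class_convex_hull(self, rng):
        minority = rng.normal(0, 1, size=(12, 2))
        majority = rng.normal(8, 1, size=(60, 2))
        X = np.vstack([minority, majority])
        y = np.array(["m"] * 12 + ["M"] * 60)
        Xb, yb = smote_augment(X, y, rng=rng)
        synth = Xb[72:]
        assert (yb[72:] == "m").all()
        hull = Delaunay(minority[ConvexHull(minority).vertices])
        assert np.all(hull.find_simplex(synth) >= 0)

    def test_singleton_class_raises(self, rng):
        X = rng.normal(size=(5, 2))
        y = np.array(["a", "b", "b", "b", "b"])
        with pytest.raises(ValueError):
            smote_augment(X, y, rng=rng)


class TestRepeatedStratifiedCV:
    def test_prediction_bookkeeping(self, cohort_df):
        table = FeatureTable.from_cohort(cohort_df)
        plan = CVPlan(n_folds=5, n_repeats=3, seed=0)
        preds = repeated_stratified_cv(table, plan, model="svc")
        assert len(preds) == 3 * 361
        # every sample predicted exactly once per repeat
        per_repeat = preds.groupby("repeat")["index"].nunique()
        assert (per_repeat == 361).all()

    def test_deterministic_under_seed(self, cohort_df):
        table = FeatureTable.from_cohort(cohort_df)
        plan = CVPlan(n_folds=5, n_repeats=2, seed=7)
        a = repeated_stratified_cv(table, plan, model="svc")
        b = repeated_stratified_cv(table, plan, model="svc")
        pd.testing.assert_frame_equal(a, b)

    def test_stratification_within_one_sample(self, cohort_df):
        table = FeatureTable.from_cohort(cohort_df)
        plan = CVPlan(n_folds=5, n_repeats=1, seed=3)
        preds = repeated_stratified_cv(table, plan, model="lda")
        global_counts = pd.Series(table.labels).value_counts()
        for _, fold in preds.groupby("fold"):
            counts = fold["true"].value_counts()
            for cls, total in global_counts.items():
                expected = total / plan.n_folds
                assert abs(counts.get(cls, 0) - expected) <= 1

    def test_validation_indices_never_in_training(self, cohort_df):
        """Leakage guard: SMOTE rows exist only inside a training fold; each
        validation index appears in exactly one fold per repeat."""
        table = FeatureTable.from_cohort(cohort_df)
        plan = CVPlan(n_folds=5, n_repeats=2, seed=5)
        preds = repeated_stratified_cv(table, plan, model="knn")
        for _, rep in preds.groupby("repeat"):
            fold_sets = [set(f["index"]) for _, f in rep.groupby("fold")]
            for i, a in enumerate(fold_sets):
                for b in fold_sets[i + 1 :]:
                    assert not a & b
            assert set().union(*fold_sets) == set(range(361))

    def test_perfectly_separated_classes_near_perfect(self):
        table = toy_table()
        preds = repeated_stratified_cv(table, CVPlan(5, 2, seed=1), model="svc")
        acc = (preds["true"] == preds["predicted"]).mean()
        assert acc > 0.99

    def test_class_smaller_than_folds_raises(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(14, 3))
        y = np.array(["a"] * 10 + ["b"] * 4)
        table = FeatureTable(X, y, np.arange(14).astype(str))
        with pytest.raises(ValueError):
            repeated_stratified_cv(table, CVPlan(5, 1, seed=0))

    def test_permutation_null_macro_f_near_chance(self, cohort_df):
        rng = np.random.default_rng(123)
        shuffled = cohort_df.copy()
        shuffled["group"] = rng.permutation(shuffled["group"].to_numpy())
        table = FeatureTable.from_cohort(shuffled)
        preds = repeated_stratified_cv(table, CVPlan(5, 3, seed=2), model="svc")
        assert macro_f_score(preds) == pytest.approx(1 / 5, abs=0.07)


class TestConfusionAggregation:
    def test_perfect_predictions_identity(self):
        preds = pd.DataFrame(
            {"true": ["A"] * 5 + ["B"] * 5, "predicted": ["A"] * 5 + ["B"] * 5}
        )
        s = aggregate_confusion(preds, classes=("A", "B"))
        assert np.all(np.diag(s.counts) == 5)
        assert s.sensitivity == {"A": 100.0, "B": 100.0}
        assert s.specificity == {"A": 100.0, "B": 100.0}

    def test_sensitivity_arithmetic(self):
        preds = pd.DataFrame(
            {
                "true": ["CTL"] * 100 + ["HGG"] * 50,
                "predicted": ["CTL"] * 87 + ["HGG"] * 13 + ["HGG"] * 50,
            }
        )
        s = aggregate_confusion(preds)
        assert s.sensitivity["CTL"] == pytest.approx(87.0)

    def test_row_normalization_sums_to_one(self, cohort_df):
        table = FeatureTable.from_cohort(cohort_df)
        preds = repeated_stratified_cv(table, CVPlan(5, 1, seed=0), model="svc")
        s = aggregate_confusion(preds)
        np.testing.assert_allclose(s.detection_probability.sum(axis=1), 1.0)
        assert s.total == 361

    def test_se_sp_consistent_with_counts(self):
        rng = np.random.default_rng(8)
        preds = pd.DataFrame(
            {
                "true": rng.choice(["A", "B", "C"], size=300),
                "predicted": rng.choice(["A", "B", "C"], size=300),
            }
        )
        s = aggregate_confusion(preds, classes=("A", "B", "C"))
        for i, c in enumerate(s.classes):
            tp = s.counts[i, i]
            fn = s.counts[i].sum() - tp
            fp = s.counts[:, i].sum() - tp
            tn = s.counts.sum() - tp - fn - fp
            assert s.sensitivity[c] == pytest.approx(100 * tp / (tp + fn))
            assert s.specificity[c] == pytest.approx(100 * tn / (tn + fp))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_confusion(pd.DataFrame({"true": [], "predicted": []}))


class TestModelZoo:
    def test_threshold_label_learned_by_every_model(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-1, 1, size=(120, 1))
        X = np.hstack([x, rng.normal(size=(120, 2)) * 0.01])
        y = np.where(x[:, 0] > 0, "hi", "lo")
        table = FeatureTable(X, y, np.arange(120).astype(str))
        ranking = model_zoo_evaluate(table, CVPlan(5, 1, seed=0))
        assert set(ranking["model"]) == {
            "lda", "logreg", "knn", "svc", "gboost", "rforest", "etrees",
        }
        assert (ranking["macro_f"] > 0.9).all()

    def test_ranking_deterministic_under_seed(self):
        table = toy_table(n_per_class=25, separation=2.0, seed=3)
        a = model_zoo_evaluate(table, CVPlan(5, 1, seed=4))
        b = model_zoo_evaluate(table, CVPlan(5, 1, seed=4))
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_model_rejected(self, cohort_df):
        table = FeatureTable.from_cohort(cohort_df)
        with pytest.raises(ValueError):
            repeated_stratified_cv(table, CVPlan(5, 1, seed=0), model="mystery")
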
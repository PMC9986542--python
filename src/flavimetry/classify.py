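"""Multi-class tumor-entity classification from the three autofluorescence metrics.

Protocol: stratified 5-fold cross-validation repeated 50 times.  Within each
of the 250 validations the 80% training split is z-scored, minority classes
are oversampled to the majority size with SMOTE (synthetic samples are convex
combinations of a class member and one of its k within-class nearest
neighbors), a classifier is fit and the untouched 20% validation split is
predicted.  Predictions are aggregated over all validations into a single
confusion matrix with one-vs-rest sensitivity and specificity per class.

SMOTE is implemented here directly (x_new = x + u * (x_nn - x), u ~ U(0, 1));
synthetic rows exist only inside a training fold and can never leak into a
validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.svm import SVC

from .cohort import GROUPS, METRICS

__all__ = [
    "CLASS_ORDER",
    "MODEL_ZOO",
    "CVPlan",
    "ConfusionSummary",
    "FeatureTable",
    "smote_augment",
    "repeated_stratified_cv",
    "aggregate_confusion",
    "model_zoo_evaluate",
    "macro_f_score",
]

#: Display order of the classes in confusion outputs.
CLASS_ORDER = GROUPS


def _make_model(name: str, seed: int):
    factories = {
        "lda": lambda: LinearDiscriminantAnalysis(),
        "logreg": lambda: LogisticRegression(max_iter=1000),
        "knn": lambda: KNeighborsClassifier(),
        "svc": lambda: SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed),
        "gboost": lambda: GradientBoostingClassifier(random_state=seed),
        "rforest": lambda: RandomForestClassifier(random_state=seed),
        "etrees": lambda: ExtraTreesClassifier(random_state=seed),
    }
    if name not in factories:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(factories)}")
    return factories[name]()


MODEL_ZOO = ("lda", "logreg", "knn", "svc", "gboost", "rforest", "etrees")


@dataclass(frozen=True)
class CVPlan:
    """Repeated stratified k-fold plan (default: 5 folds x 50 repeats)."""

    n_folds: int = 5
    n_repeats: int = 50
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2 or self.n_repeats < 1:
            raise ValueError("need n_folds >= 2 and n_repeats >= 1")


@dataclass(frozen=True)
class FeatureTable:
    """Feature matrix (tau_ns, redox_ratio, r_flavin), labels and sample ids."""

    features: np.ndarray
    labels: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels)
        ids = np.asarray(self.ids)
        if X.ndim != 2 or X.shape[0] != y.size or ids.size != y.size:
            raise ValueError("features, labels and ids must have matching lengths")
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain missing or non-finite values")
        if np.unique(y).size < 2:
            raise ValueError("need at least two classes")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)
        object.__setattr__(self, "ids", ids)

    @classmethod
    def from_cohort(cls, cohort_df: pd.DataFrame) -> "FeatureTable":
        return cls(
            features=cohort_df[list(METRICS)].to_numpy(dtype=float),
            labels=cohort_df["group"].to_numpy(),
            ids=cohort_df["sample_id"].to_numpy(),
        )


def smote_augment(
    features: np.ndarray,
    labels: np.ndarray,
    k_neighbors: int = 5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample every minority class to the majority size with SMOTE.

    Each synthetic row is x + u * (x_nn - x) with u ~ Uniform(0, 1), x a
    class member and x_nn one of its k within-class nearest neighbors
    (k capped at class size - 1).  Already balanced input is returned
    unchanged.
    """
    if rng is None:
        rng = np.random.default_rng()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    majority = counts.max()
    if np.all(counts == majority):
        return X.copy(), y.copy()
    new_X, new_y = [X], [y]
    for cls_label, count in zip(classes, counts):
        deficit = majority - count
        if deficit == 0:
            continue
        if count < 2:
            raise ValueError(
                f"class {cls_label!r} has a single member; SMOTE needs a neighbor"
            )
        Xc = X[y == cls_label]
        k = min(k_neighbors, count - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        neighbors = nn.kneighbors(Xc, return_distance=False)[:, 1:]
        base = rng.integers(0, count, size=deficit)
        pick = rng.integers(0, k, size=deficit)
        u = rng.uniform(0.0, 1.0, size=deficit)
        anchor = Xc[base]
        partner = Xc[neighbors[base, pick]]
        new_X.append(anchor + u[:, None] * (partner - anchor))
        new_y.append(np.full(deficit, cls_label, dtype=y.dtype))
    return np.concatenate(new_X), np.concatenate(new_y)


def _zscore_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def repeated_stratified_cv(
    table: FeatureTable,
    plan: CVPlan,
    model: str = "svc",
    k_neighbors: int = 5,
) -> pd.DataFrame:
    """Run the full protocol; returns one prediction row per (repeat, sample).

    Every sample is predicted exactly once per repeat; features are z-scored
    with training-fold statistics and SMOTE is applied to the training fold
    only.  Deterministic under the plan seed.
    """
    X, y = table.features, table.labels
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < plan.n_folds:
        raise ValueError(
            f"smallest class ({counts.min()}) is below n_folds={plan.n_folds}"
        )
    master = np.random.default_rng(plan.seed)
    rows = []
    for repeat in range(plan.n_repeats):
        fold_seed = int(master.integers(0, 2**31 - 1))
        smote_rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))
        splitter = StratifiedKFold(
            n_splits=plan.n_folds, shuffle=True, random_state=fold_seed
        )
        for fold, (train_idx, val_idx) in enumerate(splitter.split(X, y)):
            X_train, y_train = X[train_idx], y[train_idx]
            mu, sd = _zscore_fit(X_train)
            Xb, yb = smote_augment(
                (X_train - mu) / sd, y_train, k_neighbors=k_neighbors, rng=smote_rng
            )
            clf = _make_model(model, seed=fold_seed)
            clf.fit(Xb, yb)
            pred = clf.predict((X[val_idx] - mu) / sd)
            for idx, p in zip(val_idx, pred):
                rows.append(
                    {
                        "repeat": repeat,
                        "fold": fold,
                        "index": int(idx),
                        "sample_id": table.ids[idx],
                        "true": y[idx],
                        "predicted": p,
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConfusionSummary:
    """Aggregated confusion counts with per-class one-vs-rest SE/SP (percent)."""

    classes: tuple[str, ...]
    counts: np.ndarray
    sensitivity: dict[str, float]
    specificity: dict[str, float]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def detection_probability(self) -> np.ndarray:
        """Row-normalized confusion matrix (rows are true classes)."""
        row_sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        row_sums[row_sums == 0] = 1.0
        return self.counts / row_sums


def aggregate_confusion(
    predictions: pd.DataFrame, classes: tuple[str, ...] | None = None
) -> ConfusionSummary:
    """Sum prediction counts over all validations and derive SE/SP per class."""
    if predictions.empty:
        raise ValueError("no predictions to aggregate")
    if classes is None:
        present = set(predictions["true"]) | set(predictions["predicted"])
        classes = tuple(g for g in CLASS_ORDER if g in present) or tuple(sorted(present))
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(predictions["true"], predictions["predicted"]):
        counts[index[t], index[p]] += 1
    total = counts.sum()
    sensitivity, specificity = {}, {}
    for c, i in index.items():
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        sensitivity[c] = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
        specificity[c] = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return ConfusionSummary(
        classes=classes, counts=counts, sensitivity=sensitivity, specificity=specificity
    )


def macro_f_score(predictions: pd.DataFrame) -> float:
    """Macro-averaged F1 over all pooled predictions."""
    return float(
        f1_score(predictions["true"], predictions["predicted"], average="macro")
    )


def model_zoo_evaluate(table: FeatureTable, plan: CVPlan) -> pd.DataFrame:
    """Macro F-score of every zoo model under the plan, best first."""
    rows = []
    for model in MODEL_ZOO:
        preds = repeated_stratified_cv(table, plan, model=model)
        rows.append({"model": model, "macro_f": macro_f_score(preds)})
    return (
        pd.DataFrame(rows)
        .sort_values("macro_f", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
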
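"""Damage-level classifiers (random forest and 1-D CNN) and the
sample-size sweep.

Trees are split 75/25 into training and test sets (stratified by damage
level by default, so small test sets keep all four levels; pass
``stratify=False`` for a plain random split). The random forest is a
bagged decision-tree ensemble with majority vote and Gini feature
importances; the CNN is a small 1-D convolutional network over the
ordered feature vector with gradient-based importances. Both are
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .cnn import Conv1DNet
from .evaluate import EvaluationReport, evaluate_predictions
from .vegindex import FeatureTable

__all__ = [
    "SplitPlan",
    "ModelSpec",
    "FittedModel",
    "make_split",
    "train_rf",
    "train_cnn",
    "train_model",
    "evaluate_on_test",
    "sample_size_sweep",
]


@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple[int, ...]
    test_ids: tuple[int, ...]
    validation_fraction: float
    stratified: bool
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters for one classifier kind.

    RF: ``n_trees`` bagged trees, unlimited depth, sqrt(m) features per
    split. CNN: see :class:`needlegrade.cnn.Conv1DNet`.
    """

    kind: str = "RF"  # "RF" or "CNN"
    n_trees: int = 500
    max_depth: int | None = None
    conv_filters: int = 16
    kernel: int = 3
    pool: int = 2
    dense: int = 32
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("RF", "CNN"):
            raise ValueError("kind must be 'RF' or 'CNN'")
        for name in ("n_trees", "conv_filters", "kernel", "pool", "dense",
                     "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FittedModel:
    spec: ModelSpec
    feature_names: list[str]
    model: object
    importances: pd.Series  # normalised to sum 1

    def predict(self, table: FeatureTable) -> np.ndarray:
        X = table.values[self.feature_names].to_numpy(dtype=float)
        return np.asarray(self.model.predict(X))


def make_split(ids: Sequence[int], labels: Sequence[int], seed: int,
               test_fraction: float = 0.25, validation_fraction: float = 0.25,
               stratify: bool = True) -> SplitPlan:
    """Deterministic stratified 75/25 train/test partition."""
    ids = np.asarray(ids)
    labels = np.asarray(labels)
    if stratify:
        counts = pd.Series(labels).value_counts()
        if counts.min() < 4:
            raise ValueError(
                f"stratified split needs >= 4 trees per class; smallest "
                f"class has {counts.min()}")
    train, test = train_test_split(
        ids, test_size=test_fraction, random_state=seed,
        stratify=labels if stratify else None, shuffle=True)
    return SplitPlan(train_ids=tuple(int(i) for i in np.sort(train)),
                     test_ids=tuple(int(i) for i in np.sort(test)),
                     validation_fraction=validation_fraction,
                     stratified=stratify, seed=seed)


def _training_arrays(table: FeatureTable, labels: pd.Series,
                     plan: SplitPlan) -> tuple[np.ndarray, np.ndarray]:
    X = table.values.loc[list(plan.train_ids)].to_numpy(dtype=float)
    y = labels.loc[list(plan.train_ids)].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("training data holds a single class")
    return X, y


def train_rf(table: FeatureTable, labels: pd.Series, plan: SplitPlan,
             spec: ModelSpec) -> FittedModel:
    """Bagged decision-tree ensemble with Gini importances (sum to 1)."""
    if spec.kind != "RF":
        raise ValueError("spec.kind must be 'RF'")
    X, y = _training_arrays(table, labels, plan)
    rf = RandomForestClassifier(
        n_estimators=spec.n_trees, max_depth=spec.max_depth,
        max_features="sqrt", bootstrap=True, oob_score=False,
        random_state=spec.seed, n_jobs=1)
    rf.fit(X, y)
    imp = rf.feature_importances_
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1 / imp.size)
    return FittedModel(spec=spec, feature_names=table.feature_names,
                       model=rf,
                       importances=pd.Series(imp, index=table.feature_names))


def train_cnn(table: FeatureTable, labels: pd.Series, plan: SplitPlan,
              spec: ModelSpec) -> FittedModel:
    """1-D CNN over the ordered feature vector; gradient importances."""
    if spec.kind != "CNN":
        raise ValueError("spec.kind must be 'CNN'")
    if len(table.feature_names) < 2:
        raise ValueError("CNN needs >= 2 features")
    X, y = _training_arrays(table, labels, plan)
    net = Conv1DNet(filters=spec.conv_filters, kernel=spec.kernel,
                    pool=spec.pool, dense=spec.dense, epochs=spec.epochs,
                    learning_rate=spec.learning_rate,
                    batch_size=spec.batch_size, seed=spec.seed)
    net.fit(X, y)
    imp = net.input_gradient_importances()
    return FittedModel(spec=spec, feature_names=table.feature_names,
                       model=net,
                       importances=pd.Series(imp, index=table.feature_names))


def train_model(table: FeatureTable, labels: pd.Series, plan: SplitPlan,
                spec: ModelSpec) -> FittedModel:
    trainer = train_rf if spec.kind == "RF" else train_cnn
    return trainer(table, labels, plan, spec)


def evaluate_on_test(fitted: FittedModel, table: FeatureTable,
                     labels: pd.Series, plan: SplitPlan,
                     metadata: Mapping | None = None) -> EvaluationReport:
    test_ids = list(plan.test_ids)
    X_test = table.values.loc[test_ids, fitted.feature_names]
    y_pred = np.asarray(fitted.model.predict(X_test.to_numpy(dtype=float)))
    y_true = labels.loc[test_ids].to_numpy()
    meta = {"model": fitted.spec.kind, "n_test": len(test_ids),
            "seed": fitted.spec.seed, **(metadata or {})}
    return evaluate_predictions(
        y_true, y_pred, labels=sorted(np.unique(labels)),
        importances=fitted.importances.to_dict(), metadata=meta)


def _stratified_subsample(ids: np.ndarray, labels: np.ndarray, size: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` ids keeping class proportions (largest-remainder)."""
    classes, counts = np.unique(labels, return_counts=True)
    exact = size * counts / counts.sum()
    take = np.floor(exact).astype(int)
    rem = size - take.sum()
    order = np.argsort(-(exact - take))
    take[order[:rem]] += 1
    out = []
    for c, n_c in zip(classes, take):
        pool = ids[labels == c]
        out.append(rng.choice(pool, size=min(n_c, pool.size), replace=False))
    return np.sort(np.concatenate(out))


def sample_size_sweep(table: FeatureTable, labels: pd.Series,
                      sizes: Sequence[int], specs: Sequence[ModelSpec],
                      seeds: Sequence[int],
                      stratify: bool = True) -> pd.DataFrame:
    """OA/Kappa over a grid of sample sizes, models and seeds.

    For each size an independent stratified subsample is drawn per seed,
    split 75/25, trained and evaluated; the result has one row per
    (size, model, seed) cell plus mean/sd summaries accessible by a
    simple groupby. Sizes too small to stratify are skipped with a
    warning row.
    """
    all_ids = table.tree_ids
    all_labels = labels.loc[all_ids].to_numpy()
    n_classes = np.unique(all_labels).size
    rows = []
    for size in sizes:
        if size > all_ids.size:
            raise ValueError(f"size {size} exceeds available trees "
                             f"({all_ids.size})")
        if size < 16 * n_classes / 4:  # >= 4 per class after the 75/25 split
            import warnings
            warnings.warn(f"size {size} below stratification minimum; skipped")
            continue
        for seed in seeds:
            rng = np.random.default_rng(np.random.SeedSequence([seed, size]))
            sub_ids = (_stratified_subsample(all_ids, all_labels, size, rng)
                       if size < all_ids.size else all_ids)
            sub_labels = labels.loc[sub_ids]
            plan = make_split(sub_ids, sub_labels.to_numpy(), seed=seed,
                              stratify=stratify)
            sub_table = FeatureTable(table.values.loc[sub_ids],
                                     normalised=table.normalised,
                                     bounds=table.bounds)
            for spec in specs:
                fitted = train_model(sub_table, sub_labels, plan,
                                     replace(spec, seed=seed))
                rep = evaluate_on_test(fitted, sub_table, sub_labels, plan)
                rows.append({"size": size, "model": spec.kind, "seed": seed,
                             "OA": rep.OA, "Kappa": rep.Kappa})
    return pd.DataFrame(rows)
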
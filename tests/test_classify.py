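"""Splitting, random-forest and CNN training, and the sample-size sweep."""

import numpy as np
import pandas as pd
import pytest

from needlegrade.classify import (ModelSpec, make_split, sample_size_sweep,
                                  train_cnn, train_model, train_rf)
from needlegrade.cnn import Conv1DNet
from needlegrade.vegindex import FeatureTable


def _separable_table(n_per_class=40, n_noise=1, seed=0):
    rng = np.random.default_rng(seed)
    levels = np.repeat([1, 2, 3, 4], n_per_class)
    n = levels.size
    df = pd.DataFrame({
        "f_signal": (levels - 1) / 3 + rng.normal(0, 0.02, n),
        "f_signal2": (4 - levels) / 3 + rng.normal(0, 0.02, n),
        **{f"f_noise{i}": rng.uniform(0, 1, n) for i in range(n_noise)},
    }, index=np.arange(n))
    return FeatureTable(df), pd.Series(levels, index=df.index)


# ----------------------------------------------------------------- split

def test_split_sizes_840():
    ids = np.arange(840)
    labels = np.repeat([1, 2, 3, 4], 210)
    plan = make_split(ids, labels, seed=0)
    assert len(plan.train_ids) == 630 and len(plan.test_ids) == 210
    assert not set(plan.train_ids) & set(plan.test_ids)


def test_split_is_deterministic():
    ids = np.arange(80)
    labels = np.repeat([1, 2, 3, 4], 20)
    assert make_split(ids, labels, seed=5) == make_split(ids, labels, seed=5)


def test_split_stratification_balance():
    ids = np.arange(84)
    labels = np.repeat([1, 2, 3, 4], 21)
    plan = make_split(ids, labels, seed=1)
    test_labels = labels[np.isin(ids, plan.test_ids)]
    for lvl in (1, 2, 3, 4):
        assert abs((test_labels == lvl).sum() - 21 * 0.25) <= 1


def test_split_rejects_tiny_classes():
    with pytest.raises(ValueError):
        make_split(np.arange(10), np.array([1] * 7 + [2] * 3), seed=0)


# -------------------------------------------------------------------- RF

def test_rf_fits_separable_data_perfectly():
    table, labels = _separable_table()
    plan = make_split(table.tree_ids, labels.to_numpy(), seed=0)
    fitted = train_rf(table, labels, plan, ModelSpec(kind="RF", seed=0))
    X_train = table.values.loc[list(plan.train_ids)].to_numpy()
    y_train = labels.loc[list(plan.train_ids)].to_numpy()
    assert (fitted.model.predict(X_train) == y_train).all()
    assert fitted.importances.sum() == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(10))
def test_rf_ranks_noise_below_signal(seed):
    table, labels = _separable_table(seed=seed)
    plan = make_split(table.tree_ids, labels.to_numpy(), seed=seed)
    fitted = train_rf(table, labels, plan,
                      ModelSpec(kind="RF", n_trees=100, seed=seed))
    assert fitted.importances["f_noise0"] < fitted.importances["f_signal"]


def test_rf_rejects_single_class():
    table, labels = _separable_table()
    plan = make_split(table.tree_ids, labels.to_numpy(), seed=0)
    with pytest.raises(ValueError):
        train_rf(table, labels.map(lambda _: 1), plan,
                 ModelSpec(kind="RF", seed=0))


def test_kind_mismatch_raises():
    table, labels = _separable_table()
    plan = make_split(table.tree_ids, labels.to_numpy(), seed=0)
    with pytest.raises(ValueError):
        train_rf(table, labels, plan, ModelSpec(kind="CNN"))
    with pytest.raises(ValueError):
        train_cnn(table, labels, plan, ModelSpec(kind="RF"))


# ------------------------------------------------------------------- CNN

def test_cnn_deterministic_predictions():
    table, labels = _separable_table()
    plan = make_split(table.tree_ids, labels.to_numpy(), seed=0)
    spec = ModelSpec(kind="CNN", epochs=30, seed=4)
    a = train_cnn(table, labels, plan, spec)
    b = train_cnn(table, labels, plan, spec)
    X = table.values.to_numpy()
    assert np.array_equal(a.model.predict(X), b.model.predict(X))
    assert np.array_equal(a.importances.to_numpy(), b.importances.to_numpy())


def test_cnn_learns_separable_classes():
    table, labels = _separable_table()
    plan = make_split(table.tree_ids, labels.to_numpy(), seed=0)
    fitted = train_cnn(table, labels, plan, ModelSpec(kind="CNN", seed=0))
    X_train = table.values.loc[list(plan.train_ids)].to_numpy()
    y_train = labels.loc[list(plan.train_ids)].to_numpy()
    train_oa = np.mean(fitted.model.predict(X_train) == y_train)
    assert train_oa >= 0.95
    assert fitted.importances.sum() == pytest.approx(1.0)


def test_cnn_softmax_rows_sum_to_one():
    table, labels = _separable_table()
    net = Conv1DNet(epochs=5, seed=0).fit(table.values.to_numpy(),
                                          labels.to_numpy())
    proba = net.predict_proba(table.values.to_numpy())
    assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-12)
    assert proba.min() >= 0


def test_cnn_requires_two_features():
    X = np.zeros((10, 1))
    with pytest.raises(ValueError):
        Conv1DNet(epochs=1).fit(X, np.repeat([1, 2], 5))


# ----------------------------------------------------------------- sweep

def test_sweep_grid_is_complete():
    table, labels = _separable_table(n_per_class=60)
    sizes = (80, 160, 240)
    specs = [ModelSpec(kind="RF", n_trees=50),
             ModelSpec(kind="CNN", epochs=20)]
    out = sample_size_sweep(table, labels, sizes, specs, seeds=[0, 1])
    assert len(out) == len(sizes) * len(specs) * 2
    got = set(map(tuple, out[["size", "model", "seed"]].to_numpy()))
    want = {(s, m, sd) for s in sizes for m in ("RF", "CNN") for sd in (0, 1)}
    assert got == want
    assert out["OA"].between(0, 1).all()


def test_sweep_full_size_uses_every_tree():
    table, labels = _separable_table(n_per_class=30)
    out = sample_size_sweep(table, labels, [120],
                            [ModelSpec(kind="RF", n_trees=50)], seeds=[3])
    assert len(out) == 1  # n == all trees: single draw, no subsampling


def test_sweep_warns_and_skips_below_minimum():
    table, labels = _separable_table(n_per_class=30)
    with pytest.warns(UserWarning):
        out = sample_size_sweep(table, labels, [8, 120],
                                [ModelSpec(kind="RF", n_trees=20)], seeds=[0])
    assert set(out["size"]) == {120}


def test_sweep_rejects_oversized_request():
    table, labels = _separable_table(n_per_class=10)
    with pytest.raises(ValueError):
        sample_size_sweep(table, labels, [400],
                          [ModelSpec(kind="RF")], seeds=[0])
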
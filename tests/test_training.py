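"""Loss closed forms, split protocol, selection rule, reproducibility."""

import numpy as np
import pytest

from deeplip.errors import ConfigError, SearchFailure
from deeplip.model import ModelConfig, featurize_samples
from deeplip.training import (ExperimentTable, TrainConfig,
                              hyperparameter_search, repeat_experiments,
                              smooth_l1_loss, split_train_val, train_model)

TINY = ModelConfig(tower_channels=(4, 8, 8), graph_hidden=8, gather_dim=8,
                   token_dim=8, head_hidden=(16, 8), dropout=0.0)


@pytest.fixture(scope="module")
def tiny_sets(small_dataset):
    samples, _, _ = small_dataset
    train, val = samples[:12], samples[12:16]
    tf = featurize_samples(train)
    vf = featurize_samples(val)
    return train, val, tf, vf


# ---------------------------------------------------------------------------
# SmoothL1
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("pred,true,beta,expected", [
    ([1.0, 2.0], [1.0, 2.0], 1.0, 0.0),
    ([0.5], [0.0], 1.0, 0.125),          # 0.5 * 0.25 / 1
    ([3.0], [0.0], 1.0, 2.5),            # 3 - 0.5
    ([0.4], [0.0], 0.5, 0.16),           # 0.5 * 0.16 / 0.5
    ([3.0], [0.0], 2.0, 2.0),            # 3 - 1
    ([-3.0], [0.0], 1.0, 2.5),           # symmetric in the residual
])
def test_smooth_l1_closed_form(pred, true, beta, expected):
    assert smooth_l1_loss(np.array(pred), np.array(true), beta) == \
        pytest.approx(expected, abs=1e-12)


def test_smooth_l1_errors():
    with pytest.raises(ValueError):
        smooth_l1_loss(np.array([]), np.array([]))
    with pytest.raises(ValueError):
        smooth_l1_loss(np.array([1.0]), np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        smooth_l1_loss(np.array([1.0]), np.array([1.0]), beta=0.0)


# ---------------------------------------------------------------------------
# Split protocol
# ---------------------------------------------------------------------------

def test_split_sizes_match_benchmark_protocol():
    # 20% of a 3772-sample pool -> 754 validation / 3018 training
    pool = list(range(3772))
    train, val = split_train_val(pool, 0.2, seed=0)
    assert len(val) == 754
    assert len(train) == 3018


def test_split_deterministic_disjoint_exhaustive():
    pool = list(range(137))
    t1, v1 = split_train_val(pool, 0.2, seed=5)
    t2, v2 = split_train_val(pool, 0.2, seed=5)
    assert t1 == t2 and v1 == v2
    assert set(t1) | set(v1) == set(pool)
    assert set(t1) & set(v1) == set()
    t3, v3 = split_train_val(pool, 0.2, seed=6)
    assert v3 != v1  # different seed, different split


def test_split_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        split_train_val([1], 0.2, seed=0)
    with pytest.raises(ValueError):
        split_train_val(list(range(10)), 1.5, seed=0)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def test_selection_rule_returns_argmin_snapshot(tiny_sets):
    train, val, tf, vf = tiny_sets
    model, history = train_model(
        train, val, TINY, TrainConfig(seed=0, max_epochs=8, patience=8),
        train_feats=tf, val_feats=vf)
    best = min(h["val_loss"] for h in history)
    preds = model.predict_featurized(vf)
    reloss = smooth_l1_loss(preds, vf.labels, 1.0)
    assert reloss == pytest.approx(best, abs=1e-6)


def test_training_is_deterministic_per_seed(tiny_sets):
    train, val, tf, vf = tiny_sets
    runs = []
    for _ in range(2):
        model, history = train_model(
            train, val, TINY, TrainConfig(seed=3, max_epochs=4, patience=4),
            train_feats=tf, val_feats=vf)
        runs.append((history, model.network.state_dict()))
    assert runs[0][0] == runs[1][0]  # bitwise-identical history
    for k in runs[0][1]:
        assert np.array_equal(runs[0][1][k], runs[1][1][k])


def test_training_requires_labels(small_dataset):
    samples, _, _ = small_dataset
    unlabelled = [type(s)(s.ligand, s.pocket, label=None, id=s.id)
                  for s in samples[:4]]
    with pytest.raises(ConfigError):
        train_model(unlabelled, unlabelled, TINY,
                    TrainConfig(max_epochs=1))


# ---------------------------------------------------------------------------
# Repeat protocol
# ---------------------------------------------------------------------------

def test_repeat_experiments_table(tiny_sets, small_dataset):
    train, val, tf, vf = tiny_sets
    test = small_dataset[0][16:]
    table, models = repeat_experiments(
        train, val, test, TINY, TrainConfig(max_epochs=3, patience=3),
        seeds=[0, 1])
    assert len(table.rows) == 2 and len(models) == 2
    agg = table.aggregate()
    for key in ("pcc", "mae", "rmse"):
        vals = [r[key] for r in table.rows]
        assert agg[key][0] == pytest.approx(np.mean(vals))
    assert table.best_seed == min(table.rows,
                                  key=lambda r: r["val_loss"])["seed"]
    df = table.to_dataframe()
    assert df["best"].sum() == 1


def test_repeat_single_seed_has_zero_sd(tiny_sets, small_dataset):
    train, val, tf, vf = tiny_sets
    test = small_dataset[0][16:]
    table, _ = repeat_experiments(train, val, test, TINY,
                                  TrainConfig(max_epochs=2, patience=2),
                                  seeds=[4])
    assert table.aggregate()["rmse"][1] == 0.0


# ---------------------------------------------------------------------------
# Hyperparameter search
# ---------------------------------------------------------------------------

def test_random_search_replayable_and_argmin(tiny_sets):
    train, val, tf, vf = tiny_sets
    space = {"token_dim": [4, 8], "dropout": (0.0, 0.2)}
    best1, log1 = hyperparameter_search(
        train, val, space, n_trials=3, seed=9, base_model_config=TINY,
        train_config=TrainConfig(max_epochs=2, patience=2))
    best2, log2 = hyperparameter_search(
        train, val, space, n_trials=3, seed=9, base_model_config=TINY,
        train_config=TrainConfig(max_epochs=2, patience=2))
    assert [t["params"] for t in log1] == [t["params"] for t in log2]
    best_val = min(t["val_loss"] for t in log1)
    assert all(t["val_loss"] >= best_val for t in log1)
    assert best1 == best2


def test_search_single_trial_returns_it(tiny_sets):
    train, val, tf, vf = tiny_sets
    best, log = hyperparameter_search(
        train, val, {"token_dim": [8]}, n_trials=1, seed=0,
        base_model_config=TINY,
        train_config=TrainConfig(max_epochs=1, patience=1))
    assert best.token_dim == 8
    assert len(log) == 1
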
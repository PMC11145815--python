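"""Training loop, split protocol, repeat-seed experiments, hyperparameter
search.

The loss is SmoothL1 (Huber-like): quadratic for residuals below ``beta``,
linear beyond.  Model selection keeps the parameter snapshot with the
minimum validation loss, not the final epoch.  The benchmark protocol
repeats training with several random seeds and flags the seed with the
best validation error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Tensor
from .complex_graph import GraphConfig
from .errors import ConfigError, DivergenceError, SearchFailure
from .evaluation import Metrics, compute_metrics
from .model import (AffinityNetwork, FeaturizedSet, ModelConfig,
                    Normalization, TrainedModel, assemble_batch,
                    featurize_samples)
from .nn import Adam
from .structure_io import ComplexSample


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 80
    patience: int = 30               # early stopping on validation loss
    beta: float = 1.0                # SmoothL1 transition point, pK units
    seed: int = 0
    val_fraction: float = 0.2

    def __post_init__(self):
        if not (0 < self.val_fraction < 1):
            raise ConfigError("val_fraction must be in (0, 1)")
        if self.beta <= 0:
            raise ConfigError("beta must be positive")


def smooth_l1_loss(predicted: np.ndarray, true: np.ndarray,
                   beta: float = 1.0) -> float:
    """Mean SmoothL1: 0.5 d^2/beta if |d| < beta else |d| - 0.5 beta."""
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true, dtype=float)
    if predicted.shape != true.shape:
        raise ValueError("predicted/true length mismatch")
    if predicted.size == 0:
        raise ValueError("empty input")
    if beta <= 0:
        raise ValueError("beta must be positive")
    d = np.abs(predicted - true)
    per = np.where(d < beta, 0.5 * d * d / beta, d - 0.5 * beta)
    return float(per.mean())


def _smooth_l1_tensor(pred: Tensor, true: np.ndarray, beta: float) -> Tensor:
    """Differentiable SmoothL1 (the quadratic/linear mask is constant)."""
    diff = pred - Tensor(true.astype(pred.data.dtype))
    absd = diff.abs()
    quad = (np.abs(diff.data) < beta).astype(pred.data.dtype)
    per = Tensor(quad) * (diff * diff) * (0.5 / beta) \
        + Tensor(1.0 - quad) * (absd - 0.5 * beta)
    return per.mean()


def split_train_val(samples: Sequence, fraction: float = 0.2,
                    seed: int = 0) -> Tuple[list, list]:
    """Random disjoint/exhaustive split; validation size floor(fraction*N)."""
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = int(math.floor(fraction * n))
    val_idx = set(perm[:n_val].tolist())
    train = [samples[i] for i in range(n) if i not in val_idx]
    val = [samples[i] for i in sorted(val_idx)]
    return train, val


def _eval_loss(model: TrainedModel, feats: FeaturizedSet,
               beta: float) -> float:
    preds = model.predict_featurized(feats)
    return smooth_l1_loss(preds, feats.labels, beta)


def train_model(train_samples: Sequence[ComplexSample],
                val_samples: Sequence[ComplexSample],
                model_config: Optional[ModelConfig] = None,
                train_config: Optional[TrainConfig] = None,
                graph_config: Optional[GraphConfig] = None,
                train_feats: Optional[FeaturizedSet] = None,
                val_feats: Optional[FeaturizedSet] = None,
                ) -> Tuple[TrainedModel, List[Dict]]:
    """Train one model; return the minimum-validation-loss snapshot.

    ``train_feats``/``val_feats`` may carry precomputed featurizations
    (shared across repeat seeds); otherwise they are computed here.
    History records per-epoch train/val loss and is bitwise reproducible
    for a fixed seed on one platform.
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    graph_config = graph_config or GraphConfig()
    need_graph = "interaction" in model_config.tokens
    if train_feats is None:
        train_feats = featurize_samples(train_samples, graph_config, need_graph)
    if val_feats is None:
        val_feats = featurize_samples(val_samples, graph_config, need_graph)
    if train_feats.labels is None or val_feats.labels is None:
        raise ConfigError("training requires labelled samples")

    seed = train_config.seed
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA5)))
    net = AffinityNetwork(model_config, seed=seed)
    net.set_rng(rng)
    norm = Normalization.fit(train_feats)
    # start the head at the mean training label so early residuals are small
    net.head[-1].lin.bias.data[:] = train_feats.labels.mean()
    model = TrainedModel(model_config, net, norm, graph_config, seed)
    opt = Adam(net.parameters(), lr=train_config.lr)

    n = len(train_feats)
    bs = min(train_config.batch_size, n)
    history: List[Dict] = []
    best_state, best_val, best_epoch = None, np.inf, -1
    for epoch in range(train_config.max_epochs):
        net.train()
        perm = rng.permutation(n)
        total, count = 0.0, 0
        for start in range(0, n, bs):
            idx = perm[start:start + bs]
            batch = assemble_batch(train_feats, idx, norm, model_config,
                                   net.dtype)
            pred = net(batch)
            loss = _smooth_l1_tensor(pred, train_feats.labels[idx],
                                     train_config.beta)
            if not np.isfinite(loss.data):
                raise DivergenceError(epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
            count += len(idx)
        val_loss = _eval_loss(model, val_feats, train_config.beta)
        if not np.isfinite(val_loss):
            raise DivergenceError(epoch)
        history.append({"epoch": epoch, "train_loss": total / count,
                        "val_loss": val_loss})
        if val_loss < best_val:
            best_val, best_epoch = val_loss, epoch
            best_state = {k: v.copy() for k, v in net.state_dict().items()}
        if epoch - best_epoch >= train_config.patience:
            break
    net.load_state_dict(best_state)
    return model, history


@dataclass
class ExperimentTable:
    """Per-seed test metrics plus the aggregate, as in the repeat protocol."""
    rows: List[Dict]                  # seed, pcc, mae, rmse, val_loss
    best_seed: int                    # minimum validation loss

    def aggregate(self) -> Dict[str, Tuple[float, float]]:
        out = {}
        for key in ("pcc", "mae", "rmse"):
            vals = np.array([r[key] for r in self.rows], dtype=float)
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            out[key] = (float(vals.mean()), sd)
        return out

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.rows)
        df["best"] = df["seed"] == self.best_seed
        return df


def repeat_experiments(train_samples, val_samples, test_samples,
                       model_config: Optional[ModelConfig] = None,
                       train_config: Optional[TrainConfig] = None,
                       n_seeds: int = 10,
                       graph_config: Optional[GraphConfig] = None,
                       seeds: Optional[Sequence[int]] = None,
                       ) -> Tuple[ExperimentTable, List[TrainedModel]]:
    """Repeat the train/select/evaluate protocol across random seeds.

    Featurization is shared across seeds.  The row trained with the
    minimum validation loss is flagged ``best`` (the selection rule used
    to pick the benchmark model).
    """
    if seeds is None:
        if n_seeds < 1:
            raise ConfigError("n_seeds must be >= 1")
        seeds = list(range(n_seeds))
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    graph_config = graph_config or GraphConfig()
    need_graph = "interaction" in model_config.tokens
    tf = featurize_samples(train_samples, graph_config, need_graph)
    vf = featurize_samples(val_samples, graph_config, need_graph)
    sf = featurize_samples(test_samples, graph_config, need_graph)

    rows, models = [], []
    for s in seeds:
        cfg = replace(train_config, seed=int(s))
        model, history = train_model(train_samples, val_samples,
                                     model_config, cfg, graph_config,
                                     train_feats=tf, val_feats=vf)
        preds = model.predict_featurized(sf)
        m = compute_metrics(preds, sf.labels)
        rows.append({"seed": int(s), "pcc": m.pcc, "mae": m.mae,
                     "rmse": m.rmse,
                     "val_loss": min(h["val_loss"] for h in history)})
        models.append(model)
    best_seed = min(rows, key=lambda r: r["val_loss"])["seed"]
    return ExperimentTable(rows, best_seed), models


def hyperparameter_search(train_samples, val_samples, space: Dict,
                          n_trials: int, seed: int = 0,
                          base_model_config: Optional[ModelConfig] = None,
                          train_config: Optional[TrainConfig] = None,
                          graph_config: Optional[GraphConfig] = None,
                          ) -> Tuple[ModelConfig, List[Dict]]:
    """Seeded random search over ``space``.

    ``space`` maps ModelConfig field names to either a list of choices or
    a (low, high) numeric range.  Returns the configuration with the
    minimum validation loss and the complete, replayable trial log.
    """
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    base = base_model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    graph_config = graph_config or GraphConfig()
    need_graph = "interaction" in base.tokens
    tf = featurize_samples(train_samples, graph_config, need_graph)
    vf = featurize_samples(val_samples, graph_config, need_graph)

    rng = np.random.default_rng(seed)
    trials: List[Dict] = []
    best_cfg, best_val = None, np.inf
    for t in range(n_trials):
        sampled = {}
        for name, choices in space.items():
            if isinstance(choices, (list, tuple)) and len(choices) == 2 \
                    and all(isinstance(c, float) for c in choices):
                sampled[name] = float(rng.uniform(*choices))
            else:
                pick = choices[int(rng.integers(len(choices)))]
                sampled[name] = pick
        cfg = replace(base, **sampled)
        record: Dict = {"trial": t, "params": dict(sampled)}
        try:
            _, history = train_model(train_samples, val_samples, cfg,
                                     train_config, graph_config,
                                     train_feats=tf, val_feats=vf)
            record["val_loss"] = min(h["val_loss"] for h in history)
        except DivergenceError as exc:
            record["error"] = str(exc)
            record["val_loss"] = np.inf
        trials.append(record)
        if record["val_loss"] < best_val:
            best_val = record["val_loss"]
            best_cfg = cfg
    if best_cfg is None or not np.isfinite(best_val):
        raise SearchFailure(
            "all trials diverged: "
            + "; ".join(str(tr.get("error")) for tr in trials))
    return best_cfg, trials
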
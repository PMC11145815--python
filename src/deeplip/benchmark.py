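"""Desk-scale benchmark protocols on the synthetic collection.

Two standard experiments, used by the test suite and the acceptance
script:

* ``learnability_experiment`` — train the full model and the no-graph
  ablation on the default synthetic collection (n = 500, noise sd 0.3 pK)
  across a few seeds and report held-out metrics.  With a positive
  planted interaction weight the no-graph variant cannot represent the
  contact term, so its held-out RMSE should exceed the full model's.
* ``overfit_experiment`` — drive the training loop on a 10-sample set for
  many epochs; an implementation with working gradients must interpolate
  (training RMSE well below 0.1 pK).
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np

from .evaluation import compute_metrics
from .model import ModelConfig, featurize_samples
from .synthetic_data import SyntheticSpec, generate_dataset
from .training import TrainConfig, split_train_val, train_model


def learnability_experiment(data_seed: int = 11,
                            n_samples: int = 500,
                            train_seeds: Sequence[int] = (0, 1, 2),
                            max_epochs: int = 80,
                            variants: Sequence[str] = ("DeepLIP", "DeepLP"),
                            ) -> Dict:
    """Held-out metrics for the full model and ablations on the default
    synthetic collection.

    The collection is split 80/20 into a modelling pool and a test set,
    and the pool again 80/20 into training and validation (the split
    protocol used throughout).  Featurization is shared across seeds.

    Returns a dict with "variants" (variant -> per-seed metric rows incl.
    the minimum validation loss), "predictions" (variant -> seed -> test
    predictions) and "test_labels".
    """
    spec = SyntheticSpec(n_samples=n_samples, seed=data_seed)
    samples, _ = generate_dataset(spec)
    pool, test = split_train_val(samples, 0.2, seed=data_seed + 1)
    train, val = split_train_val(pool, 0.2, seed=data_seed + 2)

    variants_out: Dict[str, list] = {}
    predictions: Dict[str, Dict[int, np.ndarray]] = {}
    test_labels = None
    feats_cache = {}
    for variant in variants:
        need_graph = variant != "DeepLP"
        if need_graph not in feats_cache:
            feats_cache[need_graph] = tuple(
                featurize_samples(part, need_graph=need_graph)
                for part in (train, val, test))
        tf, vf, sf = feats_cache[need_graph]
        test_labels = sf.labels
        rows = []
        predictions[variant] = {}
        for seed in train_seeds:
            model, history = train_model(
                train, val, ModelConfig(variant=variant),
                TrainConfig(seed=int(seed), max_epochs=max_epochs),
                train_feats=tf, val_feats=vf)
            preds = model.predict_featurized(sf)
            predictions[variant][int(seed)] = preds
            m = compute_metrics(preds, sf.labels)
            rows.append({"seed": int(seed), "pcc": m.pcc, "mae": m.mae,
                         "rmse": m.rmse,
                         "val_loss": min(h["val_loss"] for h in history)})
        variants_out[variant] = rows
    return {"variants": variants_out, "predictions": predictions,
            "test_labels": test_labels}


def overfit_experiment(data_seed: int = 5, n_samples: int = 10,
                       epochs: int = 500) -> Dict:
    """Train on a tiny set with no early stopping; report training RMSE."""
    spec = SyntheticSpec(n_samples=n_samples, seed=data_seed)
    samples, _ = generate_dataset(spec)
    feats = featurize_samples(samples)
    model, history = train_model(
        samples, samples, ModelConfig(),
        TrainConfig(seed=0, max_epochs=epochs, patience=epochs,
                    batch_size=n_samples),
        train_feats=feats, val_feats=feats)
    preds = model.predict_featurized(feats)
    rmse = float(np.sqrt(np.mean((preds - feats.labels) ** 2)))
    max_abs = float(np.max(np.abs(preds - feats.labels)))
    return {"train_rmse": rmse, "max_abs_error": max_abs,
            "epochs_run": len(history)}
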
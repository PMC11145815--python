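"""Regression metrics, threshold screening, and 2D feature projection.

PCC measures the linear correlation between predicted and true
affinities; MAE and RMSE measure the prediction gap in pK units.  The
screening evaluator thresholds both predictions and labels at an
activity cutoff (higher pK = more active) and reports the confusion
matrix and accuracy, as used when ranking candidate inhibitors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats


@dataclass
class Metrics:
    pcc: Optional[float]   # None when undefined (constant input vector)
    mae: float
    rmse: float
    n: int

    @property
    def pcc_defined(self) -> bool:
        return self.pcc is not None


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        """Percent of samples classified correctly."""
        return 100.0 * (self.tp + self.tn) / self.n


def compute_metrics(predicted: Sequence[float],
                    true: Sequence[float]) -> Metrics:
    """PCC, MAE and RMSE of predictions against labels.

    PCC is reported as None (explicitly undefined) when either vector is
    constant, rather than silently propagating NaN.
    """
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.shape != t.shape:
        raise ValueError("length mismatch")
    if p.size < 2:
        raise ValueError("need at least 2 samples")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(t))):
        raise ValueError("non-finite values")
    resid = p - t
    mae = float(np.abs(resid).mean())
    rmse = float(np.sqrt((resid ** 2).mean()))
    if p.std() == 0 or t.std() == 0:
        pcc = None
    else:
        pcc = float(stats.pearsonr(p, t).statistic)
    return Metrics(pcc, mae, rmse, int(p.size))


def screening_eval(predicted: Sequence[float], true: Sequence[float],
                   threshold: float) -> ConfusionMatrix:
    """Confusion matrix at one activity cutoff.

    A sample is a true inhibitor iff its label >= threshold, a predicted
    inhibitor iff its prediction >= threshold.
    """
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.shape != t.shape:
        raise ValueError("length mismatch")
    if p.size < 1:
        raise ValueError("empty input")
    pred_pos = p >= threshold
    true_pos = t >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred_pos & true_pos)),
        fp=int(np.sum(pred_pos & ~true_pos)),
        tn=int(np.sum(~pred_pos & ~true_pos)),
        fn=int(np.sum(~pred_pos & true_pos)),
        threshold=float(threshold))


def screening_eval_rank(predicted: Sequence[float], true: Sequence[float],
                        threshold: float) -> ConfusionMatrix:
    """Rank-threshold variant: the top-k predictions are called inhibitors,
    with k the number of true inhibitors at the cutoff."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.shape != t.shape:
        raise ValueError("length mismatch")
    true_pos = t >= threshold
    k = int(true_pos.sum())
    order = np.argsort(-p, kind="stable")
    pred_pos = np.zeros(p.size, dtype=bool)
    pred_pos[order[:k]] = True
    return ConfusionMatrix(
        tp=int(np.sum(pred_pos & true_pos)),
        fp=int(np.sum(pred_pos & ~true_pos)),
        tn=int(np.sum(~pred_pos & ~true_pos)),
        fn=int(np.sum(~pred_pos & true_pos)),
        threshold=float(threshold))


def threshold_sweep(predicted: Sequence[float], true: Sequence[float],
                    thresholds: Sequence[float],
                    mode: str = "value") -> List[ConfusionMatrix]:
    """One ConfusionMatrix per threshold, order preserved."""
    if len(thresholds) < 1:
        raise ValueError("need at least one threshold")
    fn = screening_eval if mode == "value" else screening_eval_rank
    return [fn(predicted, true, th) for th in thresholds]


def project_features_2d(features: np.ndarray
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """Mean-centered projection onto the top-2 principal axes.

    Returns (n, 2) coordinates and the explained-variance fractions.
    The sign of each axis is fixed so its largest-magnitude loading is
    positive, making plots reproducible.
    """
    from sklearn.decomposition import PCA

    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need an (n >= 3) x (d >= 2) matrix")
    if np.allclose(x, x[0]):
        raise ValueError("rank-0 feature matrix")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(x)
    for k in range(2):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, k] *= -1
    return coords, pca.explained_variance_ratio_.copy()
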
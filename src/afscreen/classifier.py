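"""Logistic NS/AF classification with ROC-derived decision threshold.

A logistic regression is fitted on per-window covariate vectors
(symbolic-recurrence + RR-distribution features), with features z-scored
using training statistics and a tiny ridge penalty guarding against
complete separation.  The operating point tau is not fixed at 0.5: it is
the probability threshold whose (FPR, Se) point on the training ROC curve
lies closest to the ideal corner (0, 1),

    tau = argmin sqrt(FPR^2 + (1 - Se)^2),

with ties broken toward the largest threshold (fewer false AF alarms).
A window with predicted probability strictly above tau is called AF.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LogisticModel",
    "ROCCurve",
    "ConfusionCounts",
    "fit_logistic",
    "predict_proba",
    "roc_curve",
    "optimal_threshold",
    "evaluate",
    "cross_validate",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class ROCCurve:
    """ROC operating points: (threshold, FPR, Se) per candidate threshold."""

    points: Tuple[Tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        for _, fpr, se in self.points:
            if not (0 <= fpr <= 1 and 0 <= se <= 1):
                raise ValueError("FPR and Se must lie in [0, 1]")


@dataclass
class LogisticModel:
    """Fitted logistic NS/AF model with standardization and threshold tau."""

    coefficients: np.ndarray
    intercept: float
    feature_order: Tuple[str, ...]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    tau: Optional[float] = None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "coefficients": self.coefficients.tolist(),
                    "intercept": self.intercept,
                    "feature_order": list(self.feature_order),
                    "feature_means": self.feature_means.tolist(),
                    "feature_sds": self.feature_sds.tolist(),
                    "tau": self.tau,
                },
                indent=2,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "LogisticModel":
        d = json.loads(Path(path).read_text())
        return cls(
            coefficients=np.asarray(d["coefficients"], float),
            intercept=float(d["intercept"]),
            feature_order=tuple(d["feature_order"]),
            feature_means=np.asarray(d["feature_means"], float),
            feature_sds=np.asarray(d["feature_sds"], float),
            tau=d.get("tau"),
        )


def _as_matrix(
    features: Sequence[Dict[str, float]], order: Optional[Sequence[str]] = None
) -> Tuple[np.ndarray, Tuple[str, ...]]:
    if not features:
        raise ValueError("no feature vectors given")
    if order is None:
        order = tuple(features[0].keys())
    X = np.array([[fv[name] for name in order] for fv in features], dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X, tuple(order)


def fit_logistic(
    features: Sequence[Dict[str, float]],
    labels: Sequence[int],
    ridge: float = 1e-6,
) -> LogisticModel:
    """Fit the logistic model (NS = 0, AF = 1) on standardized features.

    Features are z-scored with training mean/sd (constant features get
    sd 1 so they standardize to 0).  ``ridge`` is a small L2 penalty
    weight keeping the fit finite under complete separation; set to 0
    for pure maximum likelihood.
    """
    X, order = _as_matrix(features)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes 0 (NS) and 1 (AF)")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds = np.where(sds == 0, 1.0, sds)
    Z = (X - means) / sds
    # sklearn minimizes ||w||^2/2 + C * loss, so C = 1/ridge
    C = 1.0 / ridge if ridge > 0 else 1e12
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-10)
    clf.fit(Z, y)
    return LogisticModel(
        coefficients=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        feature_order=order,
        feature_means=means,
        feature_sds=sds,
    )


def predict_proba(
    model: LogisticModel, features: Dict[str, float] | Sequence[Dict[str, float]]
) -> np.ndarray | float:
    """Probability of AF for one feature dict or a sequence of them."""
    single = isinstance(features, dict)
    fvs = [features] if single else list(features)
    X, _ = _as_matrix(fvs, order=model.feature_order)
    Z = (X - model.feature_means) / model.feature_sds
    eta = Z @ model.coefficients + model.intercept
    p = 1.0 / (1.0 + np.exp(-eta))
    return float(p[0]) if single else p


def roc_curve(probs: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """Build the ROC curve of the rule "AF iff prob > threshold".

    Candidate thresholds are the sorted unique probabilities plus the
    sentinels 0 (everything called AF except prob 0 ties) and 1
    (nothing called AF), so the curve always reaches both corners.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("length mismatch")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("both classes required to build a ROC curve")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    thresholds = np.unique(np.concatenate([p, [0.0, 1.0]]))[::-1]
    points = []
    for thr in thresholds:
        pred = p > thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        points.append((float(thr), fp / n_neg, tp / n_pos))
    return ROCCurve(tuple(points))


def optimal_threshold(roc: ROCCurve) -> float:
    """Threshold minimizing the distance from (FPR, Se) to the corner (0, 1).

    Ties are broken by the largest threshold, i.e. the most conservative
    AF-calling operating point among equally good ones.
    """
    if not roc.points:
        raise ValueError("empty ROC curve")
    best_thr, best_d = None, np.inf
    for thr, fpr, se in roc.points:
        d = float(np.hypot(fpr, 1.0 - se))
        if d < best_d - 1e-12 or (abs(d - best_d) <= 1e-12 and thr > best_thr):
            best_thr, best_d = thr, d
    return float(best_thr)


def evaluate(predicted: Sequence[int], labels: Sequence[int]) -> Dict[str, object]:
    """Sensitivity, specificity and accuracy from 0/1 predictions.

    Undefined ratios (no positives or no negatives in ``labels``) are
    reported as None with a warning.
    """
    pred = np.asarray(predicted, dtype=int)
    y = np.asarray(labels, dtype=int)
    if pred.shape != y.shape:
        raise ValueError("length mismatch")
    counts = ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )
    se = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    sp = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else None
    if se is None or sp is None:
        warnings.warn("one class absent from labels; Se or Sp undefined")
    acc = (counts.tp + counts.tn) / counts.total if counts.total else None
    return {"Se": se, "Sp": sp, "ACC": acc, "counts": counts}


def cross_validate(
    features: Sequence[Dict[str, float]],
    labels: Sequence[int],
    k: int = 10,
    seed: int = 0,
    ridge: float = 1e-6,
) -> Dict[str, object]:
    """Stratified k-fold cross-validation of the full train/threshold recipe.

    On each training fold the model is fitted and tau selected from the
    training ROC curve only; the held-out fold is then classified at that
    tau.  The aggregate metrics pool the test-fold confusion counts.
    """
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < k:
        raise ValueError("each class must have at least k members for stratification")
    fvs = list(features)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics: List[Dict[str, object]] = []
    pooled = ConfusionCounts()
    for train_idx, test_idx in skf.split(np.zeros(len(fvs)), y):
        model = fit_logistic([fvs[i] for i in train_idx], y[train_idx], ridge=ridge)
        train_probs = predict_proba(model, [fvs[i] for i in train_idx])
        model.tau = optimal_threshold(roc_curve(train_probs, y[train_idx]))
        test_probs = predict_proba(model, [fvs[i] for i in test_idx])
        pred = (test_probs > model.tau).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics = evaluate(pred, y[test_idx])
        fold_metrics.append(metrics)
        pooled = pooled + metrics["counts"]
    aggregate = {
        "Se": pooled.tp / (pooled.tp + pooled.fn) if pooled.tp + pooled.fn else None,
        "Sp": pooled.tn / (pooled.tn + pooled.fp) if pooled.tn + pooled.fp else None,
        "ACC": pooled.total and (pooled.tp + pooled.tn) / pooled.total,
        "counts": pooled,
    }
    return {"folds": fold_metrics, "aggregate": aggregate}
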
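"""AdaBoost motion-phase classifier (normal vs FoG-affected).

Discrete SAMME boosting with depth-limited decision trees as weak
learners (defaults: ten estimators, maximum depth three, learning rate 1).
The continuous score of a phase is the weighted fraction of weak-learner
votes for the FoG class, thresholded at ``decision_threshold``.

Models are serialized to JSON (tree arrays + estimator weights) so a
trained model is a plain text artifact independent of the training
session.  Leave-one-subject-out cross-validation aggregates per-fold
metrics as mean ± sd and additionally reports totals from the summed
confusion matrix.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES
from .types import ValidationError

POSITIVE = "fog"
NEGATIVE = "normal"
_EPS = 1e-10


@dataclass
class ClassifierConfig:
    n_estimators: int = 10
    max_tree_depth: int = 3
    seed: int = 0
    decision_threshold: float = 0.5
    balance_classes: bool = False

    def validate(self) -> "ClassifierConfig":
        if self.n_estimators < 1:
            raise ValidationError("n_estimators must be >= 1")
        if self.max_tree_depth < 1:
            raise ValidationError("max_tree_depth must be >= 1")
        if not 0.0 <= self.decision_threshold <= 1.0:
            raise ValidationError("decision_threshold must be in [0, 1]")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


def _tree_to_dict(tree: DecisionTreeClassifier) -> dict:
    t = tree.tree_
    # per-node majority class in {0: normal, 1: fog}, mapped through classes_
    node_class = tree.classes_[np.argmax(t.value[:, 0, :], axis=1)]
    return {
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "node_class": node_class.tolist(),
    }


def _tree_predict(tree: dict, X: np.ndarray) -> np.ndarray:
    left = np.asarray(tree["children_left"])
    right = np.asarray(tree["children_right"])
    feat = np.asarray(tree["feature"])
    thr = np.asarray(tree["threshold"])
    node_class = np.asarray(tree["node_class"])
    idx = np.zeros(len(X), dtype=np.intp)
    while True:
        internal = left[idx] != -1
        if not np.any(internal):
            break
        rows = np.flatnonzero(internal)
        cur = idx[rows]
        go_left = X[rows, feat[cur]] <= thr[cur]
        idx[rows] = np.where(go_left, left[cur], right[cur])
    return node_class[idx]


@dataclass
class FogModel:
    """A trained boosted ensemble: serialized trees plus vote weights."""

    trees: List[dict]
    alphas: List[float]
    feature_names: List[str]
    config: ClassifierConfig

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Weighted vote fraction for the FoG class, in [0, 1]."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"feature schema mismatch: model expects {len(self.feature_names)} "
                f"features, got {X.shape[1]}")
        votes = np.zeros(len(X))
        for tree, alpha in zip(self.trees, self.alphas):
            votes += alpha * _tree_predict(tree, X)
        return votes / sum(self.alphas)

    def predict(self, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        scores = self.predict_scores(X)
        labels = np.where(scores > self.config.decision_threshold, POSITIVE, NEGATIVE)
        return labels, scores

    def to_dict(self) -> dict:
        return {"schema": "gaitcue-model-1", "trees": self.trees,
                "alphas": self.alphas, "feature_names": self.feature_names,
                "config": self.config.to_dict()}

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "FogModel":
        return cls(trees=d["trees"], alphas=[float(a) for a in d["alphas"]],
                   feature_names=list(d["feature_names"]),
                   config=ClassifierConfig.from_dict(d.get("config", {})))

    @classmethod
    def load(cls, path: str) -> "FogModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _encode_labels(y: Sequence) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "UO":
        out = np.zeros(len(y), dtype=int)
        out[y == POSITIVE] = 1
        bad = ~np.isin(y, [POSITIVE, NEGATIVE])
        if np.any(bad):
            raise ValidationError(f"unknown labels: {set(y[bad])}")
        return out
    return y.astype(int)


def train(X: np.ndarray, y: Sequence, config: ClassifierConfig | None = None,
          feature_names: Optional[List[str]] = None) -> FogModel:
    """Fit the SAMME boosting recursion; deterministic given the seed."""
    config = (config or ClassifierConfig()).validate()
    X = np.asarray(X, dtype=float)
    yi = _encode_labels(y)
    if X.ndim != 2 or len(X) != len(yi):
        raise ValidationError("X must be (n_samples, n_features) aligned with y")
    if np.any(~np.isfinite(X)):
        raise ValidationError("features contain missing/non-finite values")
    if len(np.unique(yi)) < 2:
        raise ValidationError("training data must contain both classes")
    names = list(feature_names) if feature_names is not None else list(FEATURE_NAMES)
    if len(names) != X.shape[1]:
        raise ValidationError("feature_names length must match X columns")

    n = len(yi)
    if config.balance_classes:
        w = np.where(yi == 1, 0.5 / max(1, np.sum(yi == 1)),
                     0.5 / max(1, np.sum(yi == 0)))
    else:
        w = np.full(n, 1.0 / n)

    trees: List[dict] = []
    alphas: List[float] = []
    for m in range(config.n_estimators):
        learner = DecisionTreeClassifier(max_depth=config.max_tree_depth,
                                         random_state=config.seed + m)
        learner.fit(X, yi, sample_weight=w)
        pred = learner.predict(X)
        miss = pred != yi
        err = float(np.sum(w[miss]) / np.sum(w))
        if err >= 0.5:
            if not trees:  # degenerate data: keep the single weak learner
                trees.append(_tree_to_dict(learner))
                alphas.append(1.0)
            break
        err = min(max(err, _EPS), 1.0 - _EPS)
        alpha = float(np.log((1.0 - err) / err))
        trees.append(_tree_to_dict(learner))
        alphas.append(alpha)
        if err <= _EPS:
            break
        w = w * np.exp(alpha * miss)
        w = w / np.sum(w)
    return FogModel(trees=trees, alphas=alphas, feature_names=names, config=config)


def predict(model: FogModel, fv) -> Tuple[str, float]:
    """Classify a single feature vector; returns (label, score)."""
    x = fv.as_array() if hasattr(fv, "as_array") else np.asarray(fv, dtype=float)
    labels, scores = model.predict(x[None, :])
    return str(labels[0]), float(scores[0])


def _confusion(pred: np.ndarray, truth: np.ndarray) -> dict:
    return {
        "tp": int(np.sum((pred == 1) & (truth == 1))),
        "fn": int(np.sum((pred == 0) & (truth == 1))),
        "tn": int(np.sum((pred == 0) & (truth == 0))),
        "fp": int(np.sum((pred == 1) & (truth == 0))),
    }


def _rates(c: dict) -> dict:
    sens = 100.0 * c["tp"] / (c["tp"] + c["fn"]) if c["tp"] + c["fn"] else np.nan
    spec = 100.0 * c["tn"] / (c["tn"] + c["fp"]) if c["tn"] + c["fp"] else np.nan
    total = sum(c.values())
    acc = 100.0 * (c["tp"] + c["tn"]) / total if total else np.nan
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc}


@dataclass
class CvMetrics:
    """Fold-aggregated LOSO performance, percent (mean ± sd over folds)."""

    auc_mean: float
    auc_sd: float
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    accuracy_mean: float
    accuracy_sd: float
    per_fold: List[dict] = field(default_factory=list)
    total_confusion: dict = field(default_factory=dict)
    total_accuracy: float = float("nan")
    total_sensitivity: float = float("nan")
    total_specificity: float = float("nan")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def loso_cv(X: np.ndarray, y: Sequence, groups: Sequence,
            config: ClassifierConfig | None = None) -> CvMetrics:
    """Leave-one-subject-out cross-validation: one fold per subject."""
    config = (config or ClassifierConfig()).validate()
    X = np.asarray(X, dtype=float)
    yi = _encode_labels(y)
    groups = np.asarray(groups)
    subjects = np.unique(groups)
    if len(subjects) < 2:
        raise ValidationError("LOSO needs >= 2 subjects")

    per_fold: List[dict] = []
    total = {"tp": 0, "fn": 0, "tn": 0, "fp": 0}
    for subj in subjects:
        test = groups == subj
        train_mask = ~test
        if len(np.unique(yi[train_mask])) < 2:
            warnings.warn(f"fold {subj}: single-class training set, fold skipped")
            continue
        model = train(X[train_mask], yi[train_mask], config)
        scores = model.predict_scores(X[test])
        pred = (scores > config.decision_threshold).astype(int)
        c = _confusion(pred, yi[test])
        fold = {"subject": subj.item() if hasattr(subj, "item") else subj,
                "confusion": c, **_rates(c)}
        if len(np.unique(yi[test])) == 2:
            fold["auc"] = 100.0 * float(roc_auc_score(yi[test], scores))
        else:
            fold["auc"] = np.nan
            warnings.warn(f"fold {subj}: single-class test set, AUC undefined")
        per_fold.append(fold)
        for k in total:
            total[k] += c[k]

    def agg(key):
        vals = np.array([f[key] for f in per_fold], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(np.nanmean(vals)), float(np.nanstd(vals, ddof=1))

    auc = agg("auc")
    sens = agg("sensitivity")
    spec = agg("specificity")
    acc = agg("accuracy")
    total_rates = _rates(total)
    return CvMetrics(
        auc_mean=auc[0], auc_sd=auc[1],
        sensitivity_mean=sens[0], sensitivity_sd=sens[1],
        specificity_mean=spec[0], specificity_sd=spec[1],
        accuracy_mean=acc[0], accuracy_sd=acc[1],
        per_fold=per_fold, total_confusion=total,
        total_accuracy=total_rates["accuracy"],
        total_sensitivity=total_rates["sensitivity"],
        total_specificity=total_rates["specificity"],
    )
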
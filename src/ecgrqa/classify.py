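"""Classification heads and evaluation.

Two heads mirror the two feature routes of the pipeline:

* :class:`LatentCNNClassifier` — a small CNN (three convolutional layers
  followed by six fully-connected layers, softmax output, cross-entropy
  loss, Adam) operating directly on the latent grids.
* :class:`StackedRQAClassifier` — a stacking ensemble over RQA feature
  vectors with an RBF-kernel SVM, gradient-boosted trees and RUSBoost as
  base learners and logistic regression as the meta-learner.  Meta features
  are out-of-fold base class probabilities by default; an ``insample`` mode
  reproduces the (leaky) variant that trains the meta-learner on in-sample
  base predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from ._nn import (Adam, Conv2d, Flatten, Linear, Module, ReLU, Sequential,
                  Tensor)
from ._nn.autograd import cross_entropy_logits, softmax_probs
from .io_ecg import CLASSES


@dataclass
class ClassificationResult:
    """Confusion matrix and per-class metrics in a fixed class order."""

    class_order: Tuple[str, ...]
    confusion: np.ndarray
    per_class: Dict[str, Dict[str, float]]
    accuracy: float
    undefined_metrics: bool = False

    def summary(self) -> str:
        lines = [f"accuracy: {self.accuracy:.4f}"]
        for cls in self.class_order:
            m = self.per_class[cls]
            lines.append(
                f"  {cls}: precision {m['precision']:.3f} "
                f"recall {m['recall']:.3f} f1 {m['f1']:.3f}"
            )
        return "\n".join(lines)


def evaluate(pred: Sequence[str], truth: Sequence[str],
             class_order: Sequence[str] = CLASSES) -> ClassificationResult:
    """Confusion matrix, per-class precision/recall/F1 and accuracy.

    Labels must belong to ``class_order``; metrics that would divide by
    zero are reported as 0 with ``undefined_metrics`` set.
    """
    pred, truth = list(pred), list(truth)
    if len(pred) != len(truth):
        raise ValueError("pred and truth differ in length")
    known = set(class_order)
    for lab in (*pred, *truth):
        if lab not in known:
            raise ValueError(f"unknown label {lab!r}")
    cm = _sk_confusion(truth, pred, labels=list(class_order))
    prec, rec, f1, support = precision_recall_fscore_support(
        truth, pred, labels=list(class_order), zero_division=0)
    undefined = bool(
        np.any((cm.sum(axis=0) == 0) & (np.array(support) > 0))
        or np.any(np.array(support) == 0)
    )
    per_class = {
        cls: {"precision": float(p), "recall": float(r), "f1": float(f),
              "support": int(s)}
        for cls, p, r, f, s in zip(class_order, prec, rec, f1, support)
    }
    acc = float(np.trace(cm) / cm.sum()) if cm.sum() else 0.0
    return ClassificationResult(tuple(class_order), cm, per_class, acc,
                                undefined)


# -- RUSBoost --------------------------------------------------------------

class RUSBoostClassifier(ClassifierMixin, BaseEstimator):
    """SAMME boosting with random undersampling each round.

    Every boosting round draws a class-balanced subsample (all classes cut
    to the minority-class count, sampling within each class proportionally
    to the current boosting weights), fits a shallow decision tree on it,
    and applies the usual SAMME weight update on the full training set.
    """

    def __init__(self, n_estimators: int = 50, max_depth: int = 5,
                 learning_rate: float = 1.0, random_state: Optional[int] = None):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        k = len(self.classes_)
        if k < 2:
            raise ValueError("need at least two classes")
        rng = np.random.default_rng(self.random_state)
        n = len(y_enc)
        w = np.full(n, 1.0 / n)
        n_min = np.bincount(y_enc).min()
        self.estimators_: List[DecisionTreeClassifier] = []
        self.alphas_: List[float] = []
        for it in range(self.n_estimators):
            idx_parts = []
            for c in range(k):
                members = np.flatnonzero(y_enc == c)
                p = w[members] / w[members].sum()
                take = min(n_min, len(members))
                idx_parts.append(rng.choice(members, size=take, replace=False,
                                            p=p))
            idx = np.concatenate(idx_parts)
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                random_state=int(rng.integers(2**31 - 1)))
            tree.fit(X[idx], y_enc[idx], sample_weight=w[idx])
            pred = tree.predict(X)
            err = float(w[pred != y_enc].sum())
            if err >= 1.0 - 1.0 / k:  # no better than chance: stop boosting
                break
            if err <= 0.0:  # perfect learner: include with capped vote, stop
                self.estimators_.append(tree)
                self.alphas_.append(self.learning_rate
                                    * (np.log(1e10) + np.log(k - 1)))
                break
            alpha = self.learning_rate * (np.log((1 - err) / err)
                                          + np.log(k - 1))
            self.estimators_.append(tree)
            self.alphas_.append(alpha)
            w = w * np.exp(alpha * (pred != y_enc))
            w /= w.sum()
        if not self.estimators_:  # fall back to one unweighted tree
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                random_state=int(rng.integers(2**31 - 1)))
            tree.fit(X, y_enc)
            self.estimators_ = [tree]
            self.alphas_ = [1.0]
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        votes = np.zeros((X.shape[0], len(self.classes_)))
        for tree, alpha in zip(self.estimators_, self.alphas_):
            pred = tree.predict(X)
            votes[np.arange(X.shape[0]), pred] += alpha
        total = votes.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return votes / total

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# -- stacked ensemble ------------------------------------------------------

@dataclass
class StackConfig:
    """Configuration of the stacking ensemble."""

    cv_folds: int = 5
    meta_features: str = "oof"  # "insample" trains the meta-learner on leaked fits
    seed: int = 0
    svm_C: float = 1.0
    xgb_depth: int = 3
    xgb_rounds: int = 200
    rus_estimators: int = 50

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.meta_features not in ("oof", "insample"):
            raise ValueError(f"unknown meta_features {self.meta_features!r}")


def _default_bases(cfg: StackConfig):
    return [
        # RBF kernels need commensurate feature scales, hence the scaler
        ("svm", make_pipeline(StandardScaler(),
                              SVC(kernel="rbf", C=cfg.svm_C,
                                  probability=True,
                                  random_state=cfg.seed))),
        ("xgb", XGBClassifier(max_depth=cfg.xgb_depth,
                              n_estimators=cfg.xgb_rounds,
                              learning_rate=0.1, random_state=cfg.seed,
                              n_jobs=1, verbosity=0)),
        ("rus", RUSBoostClassifier(n_estimators=cfg.rus_estimators,
                                   random_state=cfg.seed)),
    ]


class StackedRQAClassifier(ClassifierMixin, BaseEstimator):
    """Stacking ensemble with a logistic-regression meta-learner."""

    def __init__(self, base_estimators=None, cv_folds: int = 5,
                 meta_features: str = "oof", seed: int = 0):
        self.base_estimators = base_estimators
        self.cv_folds = cv_folds
        self.meta_features = meta_features
        self.seed = seed

    def _bases(self):
        bases = (self.base_estimators if self.base_estimators is not None
                 else _default_bases(StackConfig(cv_folds=self.cv_folds,
                                                 seed=self.seed)))
        if len(bases) < 2:
            raise ValueError("a stacking ensemble needs >= 2 base learners")
        return [(name, clone(est)) for name, est in bases]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        counts = np.bincount(y_enc)
        if self.meta_features == "oof" and counts.min() < self.cv_folds:
            raise ValueError(
                f"smallest class has {counts.min()} samples; "
                f"stratified {self.cv_folds}-fold meta features need at "
                f"least {self.cv_folds} per class"
            )
        self.base_models_ = self._bases()
        metas = []
        if self.meta_features == "oof":
            cv = StratifiedKFold(self.cv_folds, shuffle=True,
                                 random_state=self.seed)
            for _, est in self.base_models_:
                metas.append(cross_val_predict(clone(est), X, y_enc, cv=cv,
                                               method="predict_proba"))
        for _, est in self.base_models_:
            est.fit(X, y_enc)
            if self.meta_features == "insample":
                metas.append(est.predict_proba(X))
        Z = np.hstack(metas)
        self.meta_model_ = LogisticRegression(max_iter=2000,
                                              random_state=self.seed)
        self.meta_model_.fit(Z, y_enc)
        return self

    def _meta_input(self, X):
        X = np.asarray(X, dtype=float)
        return np.hstack([est.predict_proba(X)
                          for _, est in self.base_models_])

    def predict_proba(self, X):
        if not hasattr(self, "meta_model_"):
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.empty((0, len(self.classes_)))
        return self.meta_model_.predict_proba(self._meta_input(X))

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.asarray([], dtype=self.classes_.dtype)
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def fit_stacked(features: np.ndarray, labels: Sequence[str],
                config: Optional[StackConfig] = None) -> StackedRQAClassifier:
    """Fit the stacking ensemble on an (n, features) matrix."""
    cfg = config or StackConfig()
    clf = StackedRQAClassifier(base_estimators=_default_bases(cfg),
                               cv_folds=cfg.cv_folds,
                               meta_features=cfg.meta_features,
                               seed=cfg.seed)
    return clf.fit(features, np.asarray(labels))


# -- latent CNN ------------------------------------------------------------

class LatentCNNClassifier(ClassifierMixin, BaseEstimator):
    """CNN over latent grids: 3 conv layers, then 6 fully-connected layers.

    Input is (n, h, w) (or (n, 1, h, w)); convolutions are 3×3, stride 1,
    padding 1 with widths ``conv_widths``; the fully-connected chain ends in
    a softmax over the observed classes.  Trained with cross-entropy and
    Adam; deterministic given ``seed``.
    """

    def __init__(self, conv_widths: Tuple[int, ...] = (16, 32, 64),
                 fc_widths: Tuple[int, ...] = (256, 128, 64, 32, 16),
                 epochs: int = 200, batch_size: int = 16,
                 learning_rate: float = 1e-3, seed: int = 0):
        self.conv_widths = conv_widths
        self.fc_widths = fc_widths
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed

    @staticmethod
    def _prep(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X[:, None]
        if X.ndim != 4:
            raise ValueError("expected latents of shape (n, h, w)")
        return X

    def _normalise(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean_) / self.x_std_

    def fit(self, X, y):
        X = self._prep(X)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.x_mean_ = float(X.mean())
        self.x_std_ = float(X.std()) or 1.0
        X = self._normalise(X)
        n, c, h, w = X.shape
        rng = np.random.default_rng(self.seed)
        layers: List[Module] = []
        chs = (c,) + tuple(self.conv_widths)
        for i in range(len(self.conv_widths)):
            layers += [Conv2d(chs[i], chs[i + 1], 3, stride=1, padding=1,
                              rng=rng), ReLU()]
        layers.append(Flatten())
        dims = (self.conv_widths[-1] * h * w,) + tuple(self.fc_widths)
        for i in range(len(self.fc_widths)):
            layers += [Linear(dims[i], dims[i + 1], rng=rng), ReLU()]
        layers.append(Linear(dims[-1], len(self.classes_), rng=rng))
        self.model_ = Sequential(*layers)
        opt = Adam(self.model_.parameters(), lr=self.learning_rate)
        self.loss_curve_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            tot = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                logits = self.model_(Tensor(X[idx].astype(np.float32)))
                loss = cross_entropy_logits(logits, y_enc[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                tot += float(loss.data) * len(idx)
            self.loss_curve_.append(tot / n)
        return self

    def predict_proba(self, X):
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")
        X = self._normalise(self._prep(X))
        if X.shape[0] == 0:
            return np.empty((0, len(self.classes_)))
        return softmax_probs(self.model_(Tensor(X.astype(np.float32))).data)

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.asarray([], dtype=self.classes_.dtype)
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def train_cnn_classifier(latents: Sequence[np.ndarray], labels: Sequence[str],
                         **kwargs) -> LatentCNNClassifier:
    """Fit the latent-grid CNN; thin wrapper over the estimator."""
    X = np.stack([np.asarray(g, dtype=float) for g in latents])
    return LatentCNNClassifier(**kwargs).fit(X, np.asarray(labels))


def predict(model, inputs):
    """Predicted labels and class probabilities of a fitted head."""
    labels = model.predict(inputs)
    probs = model.predict_proba(inputs)
    return labels, probs
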
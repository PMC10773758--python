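"""Soft-voting classifier ensemble and evaluation metrics.

Five heterogeneous probability-emitting base learners — decision tree,
Gaussian naive Bayes, SVM (with probability calibration enabled), k-nearest
neighbors, and a 100-tree random forest — are fitted on the training
partition; their per-class probability matrices are averaged elementwise and
the argmax taken per sample (soft voting).  Performance is summarized by a
confusion matrix, accuracy, and macro-averaged precision/recall/F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data import DataError, Dataset

__all__ = [
    "EnsembleConfig",
    "EvalReport",
    "soft_vote",
    "fit_predict_ensemble",
    "evaluate",
]


@dataclass
class EnsembleConfig:
    """Base-learner settings; unstated hyperparameters use library defaults."""

    seed: int = 0
    knn_neighbors: int = 5
    svm_kernel: str = "rbf"
    svm_c: float = 1.0
    rf_estimators: int = 100
    hard_voting: bool = False


@dataclass
class EvalReport:
    """Confusion matrix (rows true, columns predicted) and summary metrics."""

    confusion: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    class_order: list
    runtime_seconds: float | None = None

    def to_json_dict(self) -> dict:
        return {
            "confusion": np.asarray(self.confusion).astype(int).tolist(),
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "class_order": [str(c) for c in self.class_order],
            "runtime_seconds": self.runtime_seconds,
        }


def soft_vote(probs: list[np.ndarray], class_order: list | None = None):
    """Average probability matrices across learners; argmax per sample.

    All matrices must share shape and class (column) order.  Ties break to
    the lowest class index.  Returns class labels when ``class_order`` is
    given, otherwise class indices.
    """
    if not probs:
        raise DataError("soft_vote needs at least one probability matrix")
    mats = [np.asarray(p, dtype=float) for p in probs]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise DataError("probability matrices have mismatched shapes")
    if class_order is not None and shape[1] != len(class_order):
        raise DataError(
            f"{shape[1]} probability columns for {len(class_order)} classes"
        )
    mean = np.mean(mats, axis=0)
    idx = mean.argmax(axis=1)  # argmax takes the lowest index on ties
    if class_order is None:
        return idx
    return np.array([class_order[i] for i in idx], dtype=object)


def _base_learners(config: EnsembleConfig, n_train: int):
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_svm, s_rf = (int(s) % 2**31 for s in ss.generate_state(3))
    return [
        ("decision_tree", DecisionTreeClassifier(random_state=s_tree)),
        ("naive_bayes", GaussianNB()),
        (
            "svm",
            SVC(
                kernel=config.svm_kernel,
                C=config.svm_c,
                probability=True,
                random_state=s_svm,
            ),
        ),
        (
            "knn",
            KNeighborsClassifier(
                n_neighbors=min(config.knn_neighbors, n_train)
            ),
        ),
        (
            "random_forest",
            RandomForestClassifier(
                n_estimators=config.rf_estimators, random_state=s_rf
            ),
        ),
    ]


def fit_predict_ensemble(
    train: Dataset, test: Dataset, config: EnsembleConfig | None = None
) -> tuple[list[np.ndarray], np.ndarray]:
    """Fit the five base learners on ``train`` and soft-vote on ``test``.

    Returns the per-learner probability matrices (columns in the training
    set's first-appearance class order) and the voted label predictions.
    """
    config = config or EnsembleConfig()
    if list(train.feature_ids) != list(test.feature_ids):
        raise DataError("train and test feature ids differ")
    class_order = train.classes
    label_pos = {c: i for i, c in enumerate(class_order)}
    y_codes = np.array([label_pos[v] for v in train.y])
    probs: list[np.ndarray] = []
    for _, learner in _base_learners(config, train.n_samples):
        with warnings.catch_warnings():
            # Probability=True on SVC is the documented configuration here;
            # silence the library's migration advice
            warnings.filterwarnings("ignore", category=FutureWarning)
            learner.fit(train.X, y_codes)
        pr = learner.predict_proba(test.X)
        # learner.classes_ are the integer codes sorted ascending, which is
        # exactly the first-appearance class order — columns already align
        aligned = np.zeros((test.n_samples, len(class_order)))
        for col, code in enumerate(learner.classes_):
            aligned[:, int(code)] = pr[:, col]
        probs.append(aligned)
    if config.hard_voting:
        votes = np.stack([p.argmax(axis=1) for p in probs])
        preds_idx = np.array(
            [np.bincount(votes[:, i], minlength=len(class_order)).argmax()
             for i in range(votes.shape[1])]
        )
        preds = np.array([class_order[i] for i in preds_idx], dtype=object)
    else:
        preds = soft_vote(probs, class_order)
    return probs, preds


def evaluate(y_true, y_pred, class_order) -> EvalReport:
    """Confusion matrix, accuracy, and macro-averaged P/R/F1.

    Per-class one-vs-rest precision TP/(TP+FP) and recall TP/(TP+FN) are
    averaged unweighted over classes; a class with an empty denominator
    contributes 0 (the F1 of a class with P + R = 0 is likewise 0).
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise DataError("y_true and y_pred length mismatch")
    known = set(class_order)
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        unknown = set(arr.tolist()) - known
        if unknown:
            raise DataError(f"unknown label(s) in {name}: {sorted(map(str, unknown))}")
    order = list(class_order)
    conf = confusion_matrix(y_true, y_pred, labels=order)
    acc = float(np.trace(conf) / conf.sum())
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=order, average="macro", zero_division=0
    )
    return EvalReport(
        confusion=conf,
        accuracy=acc,
        macro_precision=float(prec),
        macro_recall=float(rec),
        macro_f1=float(f1),
        class_order=order,
    )
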
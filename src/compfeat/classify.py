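"""Classifiers over composite-feature matrices, plus the AUC measure.

Three classifiers: a nearest-mean classifier scored along the line
connecting the class centroids, a 3-nearest-neighbor classifier with
inverse-distance neighbor weighting, and logistic regression with a small
ridge by default (the unregularized fit fails to converge on wide
matrices; the ``converged`` flag records this).  Higher scores always
mean "more poor-like".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .data import ExpressionDataset
from .features import feature_values

__all__ = [
    "FeatureMatrix",
    "build_feature_matrix",
    "TrainedClassifier",
    "train_classifier",
    "train_nmc",
    "train_3nn",
    "train_logistic",
    "score",
    "auc",
]

CLASSIFIER_KINDS = ("nmc", "knn3", "logistic")


@dataclass
class FeatureMatrix:
    """Samples x feature-dimensions matrix with column provenance.

    A hub feature occupies one column per hub--interactor edge; all
    other feature kinds occupy one column.
    """

    values: np.ndarray
    columns: list
    labels: np.ndarray

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.columns) != self.values.shape[1]:
            raise ValueError("column provenance length must match columns")
        if self.labels.shape != (self.values.shape[0],):
            raise ValueError("labels must have one entry per sample")


def build_feature_matrix(ds: ExpressionDataset, features,
                         activity_norm: str = "sqrt") -> FeatureMatrix:
    """Assemble the classification space for a list of features."""
    blocks, columns = [], []
    for f in features:
        vals = feature_values(ds, f, activity_norm=activity_norm)
        if vals.ndim == 1:
            blocks.append(vals[:, None])
            columns.append(f.name)
        else:
            blocks.append(vals)
            interactors = [g for g in f.member_genes if g != f.hub_gene]
            columns.extend(f"{f.name}|{g}" for g in interactors)
    values = (np.hstack(blocks) if blocks
              else np.empty((ds.n_samples, 0)))
    return FeatureMatrix(values, columns, ds.labels.copy())


@dataclass
class TrainedClassifier:
    kind: str
    columns: list
    params: dict
    converged: bool = True


def train_nmc(fm: FeatureMatrix) -> TrainedClassifier:
    """Nearest-mean classifier.

    Scoring projects a sample onto the line connecting the two class
    means; score = d(projection, good mean) - d(projection, poor mean),
    so positive scores are poor-like.  A score of exactly 0 (the
    midpoint) is classified good.
    """
    if (fm.labels == 1).sum() == 0 or (fm.labels == 0).sum() == 0:
        raise ValueError("both classes must be present in training data")
    mean_poor = fm.values[fm.labels == 1].mean(axis=0)
    mean_good = fm.values[fm.labels == 0].mean(axis=0)
    return TrainedClassifier(
        kind="nmc",
        columns=list(fm.columns),
        params={"mean_good": mean_good, "mean_poor": mean_poor},
    )


def _nmc_score(clf: TrainedClassifier, x: np.ndarray) -> np.ndarray:
    m0 = clf.params["mean_good"]
    m1 = clf.params["mean_poor"]
    w = m1 - m0
    norm2 = float(w @ w)
    if norm2 == 0:
        return np.zeros(x.shape[0])
    t = (x - m0) @ w / norm2            # position along the mean-mean line
    norm = np.sqrt(norm2)
    return (np.abs(t) - np.abs(1.0 - t)) * norm


def train_3nn(fm: FeatureMatrix, k: int = 3) -> TrainedClassifier:
    """Memorize the training matrix for k-NN scoring."""
    return TrainedClassifier(
        kind="knn3",
        columns=list(fm.columns),
        params={"train_values": fm.values.copy(),
                "train_labels": fm.labels.copy(), "k": k},
    )


def _knn_score(clf: TrainedClassifier, x: np.ndarray) -> np.ndarray:
    train = clf.params["train_values"]
    labels = clf.params["train_labels"]
    k = min(clf.params["k"], train.shape[0])
    scores = np.empty(x.shape[0])
    for i, row in enumerate(x):
        d = np.sqrt(((train - row) ** 2).sum(axis=1))
        nn = np.argsort(d, kind="stable")[:k]
        dn = d[nn]
        zero = dn <= 1e-12
        if zero.any():
            w = zero.astype(float) / zero.sum()
        else:
            inv = 1.0 / dn
            w = inv / inv.sum()
        scores[i] = float(w @ labels[nn])
    return scores


def train_logistic(fm: FeatureMatrix, ridge: float = 1e-4,
                   max_iter: int = 200) -> TrainedClassifier:
    """Logistic regression with an optional L2 ridge.

    ``ridge=0`` reproduces the unregularized maximum-likelihood fit,
    which does not converge on wide matrices (weights diverge on
    separable data); the ``converged`` flag records whether the
    optimizer hit its tolerance.  Non-converged classifiers should be
    excluded from evaluation summaries.
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import LogisticRegression

    if (fm.labels == 1).sum() == 0 or (fm.labels == 0).sum() == 0:
        raise ValueError("both classes must be present in training data")
    model = LogisticRegression(C=(1.0 / ridge if ridge > 0 else np.inf),
                               solver="lbfgs", max_iter=max_iter)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(fm.values, fm.labels)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(fm.values, fm.labels)
    if converged and np.max(model.n_iter_) >= max_iter:
        converged = False
    if converged and ridge == 0:
        # perfect separation: the unregularized MLE is at infinity, so the
        # optimizer's stopping rule does not certify a finite optimum
        margins = (2 * fm.labels - 1) * model.decision_function(fm.values)
        if np.all(margins > 0):
            converged = False
    return TrainedClassifier(
        kind="logistic",
        columns=list(fm.columns),
        params={"coef": model.coef_[0].copy(),
                "intercept": float(model.intercept_[0])},
        converged=converged,
    )


def _logistic_score(clf: TrainedClassifier, x: np.ndarray) -> np.ndarray:
    return x @ clf.params["coef"] + clf.params["intercept"]


_TRAINERS = {"nmc": train_nmc, "knn3": train_3nn, "logistic": train_logistic}
_SCORERS = {"nmc": _nmc_score, "knn3": _knn_score, "logistic": _logistic_score}


def train_classifier(fm: FeatureMatrix, kind: str, **kwargs
                     ) -> TrainedClassifier:
    try:
        trainer = _TRAINERS[kind]
    except KeyError:
        raise ValueError(f"unknown classifier kind {kind!r}") from None
    return trainer(fm, **kwargs)


def score(clf: TrainedClassifier, fm: FeatureMatrix) -> np.ndarray:
    """Per-sample poor-likeness score; rejects mismatched provenance."""
    if list(fm.columns) != list(clf.columns):
        raise ValueError("feature-matrix columns do not match the "
                         "classifier's training columns")
    return _SCORERS[clf.kind](clf, fm.values)


def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney form.

    P(score_poor > score_good) + 0.5 P(equal) over all poor/good pairs
    (average tied ranks implement the half-credit convention).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
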
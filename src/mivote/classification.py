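"""Two-class learners and the one-vs-one majority-vote three-class scheme.

Three binary classifiers are trained, one per class pair (LH/RH, LH/F,
RH/F), each on its own SFFS-selected feature subset.  Their predictions
are combined by a fixed vote table:

    ========  ========  ========  ======
    LH/RH     LH/F      RH/F      output
    ========  ========  ========  ======
    LH        LH        any       LH
    RH        any       RH        RH
    any       F         F         F
    (all other combinations)      NONE
    ========  ========  ========  ======

Two of the eight possible prediction triples are contradictory and map to
the reject label NONE.  A plain multi-class k-nearest-neighbour path (no
pairing, no selection) is also provided as a baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from mivote.dataset_io import ClassLabel
from mivote.feature_matrix import FeatureMatrix
from mivote.selection import CLASS_PAIRS

__all__ = [
    "PairModel",
    "VotingClassifier",
    "make_estimator",
    "train_pair",
    "vote",
]


def make_estimator(learner: str, svm_c: float = 1.0, knn_k: int = 5):
    """Instantiate a two-class learner by name (``lda``, ``svm`` or ``knn``).

    LDA uses a shared-covariance discriminant with a tiny relative
    shrinkage ridge so near-singular pooled covariances (small folds) stay
    invertible; SVM is a linear-kernel margin hyperplane.
    """
    learner = learner.lower()
    if learner == "lda":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-6)
    if learner == "svm":
        return SVC(kernel="linear", C=svm_c)
    if learner == "knn":
        return KNeighborsClassifier(n_neighbors=knn_k)
    raise ValueError(f"unknown learner {learner!r}; expected lda, svm or knn")


@dataclass
class PairModel:
    """A fitted binary classifier for one class pair.

    Only predicts its own two labels; applies only its own selected
    feature columns.
    """

    pair: tuple[str, str]
    learner: str
    estimator: object
    feature_indices: list[int] = field(default_factory=list)

    def predict(self, values: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(values)[:, self.feature_indices]
        pred = np.asarray(self.estimator.predict(x))
        bad = set(pred) - set(self.pair)
        if bad:
            raise ValueError(f"pair model {self.pair} predicted foreign labels {bad}")
        return pred

    def decision_scores(self, values: np.ndarray) -> np.ndarray:
        """Continuous score toward the pair's second label (for ROC)."""
        x = np.atleast_2d(values)[:, self.feature_indices]
        if hasattr(self.estimator, "decision_function"):
            return np.asarray(self.estimator.decision_function(x)).ravel()
        proba = np.asarray(self.estimator.predict_proba(x))
        classes = list(self.estimator.classes_)
        return proba[:, classes.index(self.pair[1])]


def train_pair(
    features: FeatureMatrix,
    pair: tuple[str, str],
    learner: str = "lda",
    feature_indices: Sequence[int] | None = None,
    svm_c: float = 1.0,
    knn_k: int = 5,
) -> PairModel:
    """Fit one binary classifier on the trials of ``pair``.

    ``feature_indices`` restricts training and prediction to an
    SFFS-selected subset; by default all features are used.
    """
    sub = features.restrict_classes(pair)
    y = sub.label_array()
    counts = [int((y == c).sum()) for c in pair]
    if min(counts) < 2:
        raise ValueError(f"need >= 2 trials per class for pair {pair}, got {counts}")
    idx = list(feature_indices) if feature_indices is not None else list(range(sub.n_features))
    if idx and (min(idx) < 0 or max(idx) >= sub.n_features):
        raise IndexError(f"feature indices {idx} out of range for {sub.n_features} features")
    est = make_estimator(learner, svm_c=svm_c, knn_k=knn_k)
    est.fit(sub.values[:, idx], y)
    return PairModel(pair=tuple(pair), learner=learner, estimator=est, feature_indices=idx)


def vote(pred_lh_rh: str, pred_lh_f: str, pred_rh_f: str) -> ClassLabel:
    """Combine the three pair predictions by the majority-vote table.

    LH wins when both LH-capable classifiers say LH; RH and F likewise.
    The two contradictory triples yield NONE.
    """
    p1 = pred_lh_rh.value if isinstance(pred_lh_rh, ClassLabel) else pred_lh_rh
    p2 = pred_lh_f.value if isinstance(pred_lh_f, ClassLabel) else pred_lh_f
    p3 = pred_rh_f.value if isinstance(pred_rh_f, ClassLabel) else pred_rh_f
    for pred, pair in ((p1, ("LH", "RH")), (p2, ("LH", "F")), (p3, ("RH", "F"))):
        if pred not in pair:
            raise ValueError(f"prediction {pred!r} outside pair alphabet {pair}")
    if p1 == "LH" and p2 == "LH":
        return ClassLabel.LH
    if p1 == "RH" and p3 == "RH":
        return ClassLabel.RH
    if p2 == "F" and p3 == "F":
        return ClassLabel.F
    return ClassLabel.NONE


@dataclass
class VotingClassifier:
    """Three fitted pair models plus the vote rule."""

    models: dict[tuple[str, str], PairModel]

    def __post_init__(self) -> None:
        missing = [p for p in CLASS_PAIRS if p not in self.models]
        if missing:
            raise ValueError(f"missing pair models for {missing}")

    def predict(self, values: np.ndarray) -> list[ClassLabel]:
        """Vote outcome for each row of ``values`` (full feature matrix)."""
        values = np.atleast_2d(values)
        preds = {pair: self.models[pair].predict(values) for pair in CLASS_PAIRS}
        return [
            vote(
                preds[("LH", "RH")][i],
                preds[("LH", "F")][i],
                preds[("RH", "F")][i],
            )
            for i in range(values.shape[0])
        ]

    def predict_trial(self, row: np.ndarray) -> ClassLabel:
        """Vote outcome for a single trial's feature row."""
        return self.predict(np.atleast_2d(row))[0]
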
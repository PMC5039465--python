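"""Sequential forward floating selection (SFFS), run once per class pair.

SFFS grows a feature subset by repeatedly adding the candidate that most
improves a criterion J, then ("floating") removing any member whose
removal improves J further.  The conditional backward step solves the
nesting problem of plain forward selection: a feature added early can be
discarded later once better companions arrive.  Both moves require a
strict improvement, so J increases at every accepted step and the search
terminates without revisiting a subset.

The criterion used for the pipeline is the stratified inner-cross-
validated accuracy of the pair's own classifier on the candidate subset,
evaluated on training data only, so no information leaks from the outer
test fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from mivote.feature_matrix import FeatureMatrix

__all__ = ["SelectionResult", "sffs", "pairwise_select", "cv_criterion", "CLASS_PAIRS"]

#: The three one-vs-one class pairs, in vote-table order.
CLASS_PAIRS: list[tuple[str, str]] = [("LH", "RH"), ("LH", "F"), ("RH", "F")]

Criterion = Callable[[tuple[int, ...]], float]


@dataclass
class SelectionResult:
    """Outcome of one SFFS run.

    ``criterion_trace`` records J after every accepted add/remove; it is
    strictly increasing by construction.
    """

    selected: list[int]
    criterion_trace: list[float]
    pair: tuple[str, str] | None = None
    feature_names: list[str] = field(default_factory=list)


def sffs(
    criterion: Criterion,
    n_features: int,
    max_features: int = 25,
    pair: tuple[str, str] | None = None,
    feature_names: Sequence[str] | None = None,
) -> SelectionResult:
    """Run SFFS over ``n_features`` candidates.

    ``criterion`` maps a tuple of feature indices (possibly empty) to a
    finite score J; higher is better.  Ties in the argmax are broken
    toward the lowest feature index for determinism.
    """
    if n_features < 1:
        raise ValueError("need at least one candidate feature")

    cache: dict[frozenset, float] = {}

    def j_of(subset: tuple[int, ...]) -> float:
        key = frozenset(subset)
        if key not in cache:
            val = float(criterion(tuple(sorted(subset))))
            if not np.isfinite(val):
                raise ValueError(f"criterion returned non-finite J for subset {sorted(subset)}")
            cache[key] = val
        return cache[key]

    current: list[int] = []
    j_cur = j_of(())
    trace: list[float] = []

    while True:
        # forward step: best single addition
        best_add, best_j = None, j_cur
        if len(current) < max_features:
            for cand in range(n_features):
                if cand in current:
                    continue
                j_new = j_of(tuple(current + [cand]))
                if j_new > best_j:
                    best_add, best_j = cand, j_new
        if best_add is None:
            break
        current.append(best_add)
        j_cur = best_j
        trace.append(j_cur)

        # conditional backward steps: remove while removal strictly improves
        while len(current) > 1:
            best_rm, best_j = None, j_cur
            for cand in current:
                subset = tuple(i for i in current if i != cand)
                j_new = j_of(subset)
                if j_new > best_j:
                    best_rm, best_j = cand, j_new
            if best_rm is None:
                break
            current.remove(best_rm)
            j_cur = best_j
            trace.append(j_cur)

    names = list(feature_names) if feature_names is not None else []
    return SelectionResult(
        selected=sorted(current),
        criterion_trace=trace,
        pair=pair,
        feature_names=[names[i] for i in sorted(current)] if names else [],
    )


def cv_criterion(
    features: FeatureMatrix,
    estimator,
    inner_folds: int = 5,
    seed: int = 0,
) -> Criterion:
    """Stratified inner-CV accuracy criterion for a two-class problem.

    The empty subset scores the majority-class rate (what a no-feature
    classifier achieves), so only features beating that baseline are
    improving first additions; class-blind features never enter.
    """
    x_all = features.values
    y = features.label_array()
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"criterion expects exactly two classes, got {list(classes)}")
    counts = [int((y == c).sum()) for c in classes]
    if min(counts) < 2:
        raise ValueError(f"need >= 2 trials per class, got counts {counts}")
    folds = min(inner_folds, min(counts))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x_all, y))

    baseline = max(counts) / len(y)

    def criterion(subset: tuple[int, ...]) -> float:
        if not subset:
            return baseline
        x = x_all[:, list(subset)]
        correct = 0
        for train_idx, test_idx in splits:
            est = clone(estimator)
            est.fit(x[train_idx], y[train_idx])
            correct += int((est.predict(x[test_idx]) == y[test_idx]).sum())
        return correct / len(y)

    return criterion


def pairwise_select(
    features: FeatureMatrix,
    estimator_factory: Callable[[], object],
    inner_folds: int = 5,
    max_features: int = 25,
    seed: int = 0,
    pairs: Sequence[tuple[str, str]] = tuple(CLASS_PAIRS),
) -> dict[tuple[str, str], SelectionResult]:
    """One independent SFFS run per class pair.

    At prediction time only the stored indices are applied; SFFS never
    sees test data.
    """
    present = set(features.labels)
    results: dict[tuple[str, str], SelectionResult] = {}
    for pair in pairs:
        if not set(pair) <= present:
            raise ValueError(f"pair {pair} not fully present in labels {sorted(present)}")
        sub = features.restrict_classes(pair)
        crit = cv_criterion(sub, estimator_factory(), inner_folds=inner_folds, seed=seed)
        results[pair] = sffs(
            crit,
            n_features=features.n_features,
            max_features=max_features,
            pair=pair,
            feature_names=features.feature_names,
        )
    return results
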
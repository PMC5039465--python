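"""Cross-validated evaluation: accuracy, kappa, ITR, ROC and parameter sweeps.

The evaluation protocol is stratified k-fold cross-validation (9 folds by
default, chosen so the trial counts split without remainder).  Feature
extraction is trial-local, so it runs once; feature *selection* and
classifier fitting happen inside each training fold only.  Reject (NONE)
votes count as errors by default: the denominator of the accuracy never
shrinks.

Two parameter sweeps mirror the design-exploration protocol: an
offset-by-window-length grid (11 x 11 = 121 configurations by default)
and frequency-band sweeps that vary the FFT feature band with the AR
sub-bands held fixed, and vice versa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold

from mivote.config import PipelineConfig
from mivote.dataset_io import ClassLabel, EpochSet
from mivote.feature_matrix import FeatureMatrix
from mivote.pipeline import extract_features, fit_on_features
from mivote.selection import CLASS_PAIRS

__all__ = [
    "CvReport",
    "ItrParams",
    "RocResult",
    "SweepResult",
    "DEFAULT_OFFSETS",
    "DEFAULT_WINDOW_LENGTHS",
    "accuracy",
    "kappa",
    "itr",
    "kfold_cv",
    "roc_analysis",
    "sweep_offset_window",
    "sweep_bands",
]

#: Default sweep axes: offsets -0.5..0.5 s step 0.1, windows 1..3 s step 0.2.
DEFAULT_OFFSETS = [round(-0.5 + 0.1 * i, 1) for i in range(11)]
DEFAULT_WINDOW_LENGTHS = [round(1.0 + 0.2 * i, 1) for i in range(11)]

_CLASSES = ["LH", "RH", "F"]


def accuracy(preds: Sequence, truth: Sequence) -> float:
    """Percentage of correct predictions; NONE rejects never match."""
    if len(preds) == 0:
        raise ValueError("empty prediction list")
    if len(preds) != len(truth):
        raise ValueError(f"{len(preds)} predictions vs {len(truth)} truths")
    p = [x.value if isinstance(x, ClassLabel) else str(x) for x in preds]
    t = [x.value if isinstance(x, ClassLabel) else str(x) for x in truth]
    if "NONE" in t:
        raise ValueError("truth labels may not contain NONE")
    correct = sum(a == b for a, b in zip(p, t))
    return 100.0 * correct / len(t)


def kappa(observed_accuracy: float, chance: float = 1.0 / 3.0) -> float:
    """Cohen's kappa: (Pr(a) - Pr(e)) / (1 - Pr(e)), both as fractions.

    The default chance level 1/3 is for three balanced classes.
    """
    if not 0.0 < chance < 1.0:
        raise ValueError(f"chance must be in (0, 1), got {chance}")
    return (observed_accuracy - chance) / (1.0 - chance)


@dataclass
class ItrParams:
    """Inputs of the information-transfer-rate formula."""

    L: float  # decisions per minute
    p: float  # decision accuracy as a fraction
    N_targets: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.N_targets < 2:
            raise ValueError("need at least two targets")
        if self.L <= 0:
            raise ValueError("L must be positive")


def itr(params: ItrParams) -> float:
    """Information transfer rate in bits/min.

    ITR = L * [p*log2(p) + log2(N) + (1-p)*log2((1-p)/(N-1))], with the
    0*log(0) terms taken as 0, so p=1 gives L*log2(N) and p=1/N gives 0.
    """
    p, n, big_l = params.p, params.N_targets, params.L
    bits = math.log2(n)
    if p > 0.0:
        bits += p * math.log2(p)
    if p < 1.0:
        bits += (1.0 - p) * math.log2((1.0 - p) / (n - 1))
    return big_l * bits


@dataclass
class CvReport:
    """Aggregated cross-validation outcome."""

    fold_accuracies: list[float]
    mean_accuracy: float
    kappa: float
    confusion: pd.DataFrame  # rows true class, columns LH/RH/F/NONE
    pair_true_decisions: dict[tuple[str, str], int]
    seed: int
    k: int
    pair_scores: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    pair_truths: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "fold_accuracies": [round(a, 4) for a in self.fold_accuracies],
            "mean_accuracy": round(self.mean_accuracy, 4),
            "kappa": round(self.kappa, 4),
            "confusion": {
                str(idx): {c: int(v) for c, v in row.items()}
                for idx, row in self.confusion.iterrows()
            },
            "pair_true_decisions": {
                "/".join(pair): int(n) for pair, n in self.pair_true_decisions.items()
            },
        }


ModelFactory = Callable[[FeatureMatrix, PipelineConfig, int], object]


def kfold_cv(
    epochs: EpochSet,
    cfg: PipelineConfig | None = None,
    k: int | None = None,
    seed: int = 0,
    model_factory: ModelFactory | None = None,
    collect_scores: bool = False,
) -> CvReport:
    """Stratified k-fold cross-validation of the full pipeline.

    Folds are assigned by a seeded stratified shuffle.  ``model_factory``
    may replace the default pipeline fit (it receives the training-fold
    feature matrix and must return an object with
    ``predict_features(fm) -> labels``); it exists for baselines and
    stubs.  ``collect_scores`` additionally gathers per-pair decision
    scores on the test folds for ROC analysis.
    """
    cfg = cfg or PipelineConfig()
    if k is None:
        k = cfg.cv.folds
    labels = epochs.label_array()
    counts = {c: int((labels == c).sum()) for c in np.unique(labels)}
    if k > min(counts.values()):
        raise ValueError(
            f"k={k} exceeds the smallest per-class trial count {min(counts.values())}"
        )
    if epochs.n_trials % k != 0:
        divisors = [d for d in range(2, epochs.n_trials + 1) if epochs.n_trials % d == 0]
        raise ValueError(
            f"{epochs.n_trials} trials do not split into {k} equal folds; "
            f"compatible fold counts: {divisors[:8]}"
        )

    fm = extract_features(epochs, cfg)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)

    fold_accs: list[float] = []
    confusion = pd.DataFrame(
        0, index=_CLASSES, columns=_CLASSES + ["NONE"], dtype=int
    )
    pair_true = {pair: 0 for pair in CLASS_PAIRS}
    scores_acc: dict[tuple[str, str], list[np.ndarray]] = {p: [] for p in CLASS_PAIRS}
    truths_acc: dict[tuple[str, str], list[np.ndarray]] = {p: [] for p in CLASS_PAIRS}

    for train_idx, test_idx in skf.split(fm.values, labels):
        train_fm = FeatureMatrix(
            values=fm.values[train_idx],
            feature_names=list(fm.feature_names),
            labels=[fm.labels[i] for i in train_idx],
        )
        test_fm = FeatureMatrix(
            values=fm.values[test_idx],
            feature_names=list(fm.feature_names),
            labels=[fm.labels[i] for i in test_idx],
        )
        if model_factory is not None:
            model = model_factory(train_fm, cfg, seed)
        else:
            model = fit_on_features(train_fm, cfg, seed=seed)
        preds = model.predict_features(test_fm)
        truth = test_fm.labels
        fold_accs.append(accuracy(preds, truth))
        for pr, tr in zip(preds, truth):
            pr = pr.value if isinstance(pr, ClassLabel) else str(pr)
            confusion.loc[tr, pr] += 1

        voting = getattr(model, "voting", None)
        if voting is not None:
            for pair, pm in voting.models.items():
                mask = np.isin(np.asarray(truth), pair)
                if mask.any():
                    pp = pm.predict(test_fm.values[mask])
                    pair_true[pair] += int((pp == np.asarray(truth)[mask]).sum())
                if collect_scores and mask.any():
                    scores_acc[pair].append(pm.decision_scores(test_fm.values[mask]))
                    truths_acc[pair].append(np.asarray(truth)[mask])

    mean_acc = float(np.mean(fold_accs))
    report = CvReport(
        fold_accuracies=fold_accs,
        mean_accuracy=mean_acc,
        kappa=kappa(mean_acc / 100.0),
        confusion=confusion,
        pair_true_decisions=pair_true,
        seed=seed,
        k=k,
    )
    if collect_scores:
        report.pair_scores = {
            p: np.concatenate(v) if v else np.array([]) for p, v in scores_acc.items()
        }
        report.pair_truths = {
            p: np.concatenate(v) if v else np.array([]) for p, v in truths_acc.items()
        }
    return report


@dataclass
class RocResult:
    """ROC curve points and trapezoidal area under the curve."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_analysis(scores: np.ndarray, truth: Sequence, positive_label=None) -> RocResult:
    """ROC over score thresholds for a two-class truth vector."""
    truth = np.asarray([t.value if isinstance(t, ClassLabel) else str(t) for t in truth])
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores contain non-finite values")
    classes = np.unique(truth)
    if len(classes) != 2:
        raise ValueError(f"ROC needs exactly two classes, got {list(classes)}")
    if positive_label is None:
        positive_label = classes[-1]
    fpr, tpr, thr = _roc_curve(truth, scores, pos_label=positive_label)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_auc(fpr, tpr)))


@dataclass
class SweepResult:
    """Accuracy grid of an offset-by-window sweep plus its argmax cell."""

    table: pd.DataFrame  # index: window length (s), columns: offset (s)
    best_offset: float
    best_length: float
    best_accuracy: float

    @property
    def n_cells(self) -> int:
        return self.table.size


def sweep_offset_window(
    epochs: EpochSet,
    cfg: PipelineConfig | None = None,
    offsets: Sequence[float] | None = None,
    window_lengths: Sequence[float] | None = None,
    k: int | None = None,
    seed: int = 0,
    model_factory: ModelFactory | None = None,
) -> SweepResult:
    """Mean CV accuracy for every (offset, window length) cell.

    Selection and training re-run from scratch inside every cell.  Cells
    whose window falls outside the trial bounds are marked NaN (invalid),
    never silently skipped.
    """
    cfg = cfg or PipelineConfig()
    offsets = list(offsets) if offsets is not None else list(DEFAULT_OFFSETS)
    window_lengths = (
        list(window_lengths) if window_lengths is not None else list(DEFAULT_WINDOW_LENGTHS)
    )
    table = pd.DataFrame(index=window_lengths, columns=offsets, dtype=float)
    for length in window_lengths:
        for off in offsets:
            cell_cfg = cfg.replace(
                window=type(cfg.window)(
                    offset=off, length=length, anchor=cfg.window.anchor
                )
            )
            try:
                rep = kfold_cv(
                    epochs, cell_cfg, k=k, seed=seed, model_factory=model_factory
                )
                table.loc[length, off] = rep.mean_accuracy
            except ValueError as exc:
                if "outside trial" in str(exc) or "must be in" in str(exc):
                    table.loc[length, off] = np.nan
                else:
                    raise
    if table.notna().values.any():
        flat = table.stack()
        best_length, best_offset = flat.idxmax()
        best_acc = float(flat.max())
    else:
        raise ValueError("every sweep cell was invalid against the trial bounds")
    return SweepResult(
        table=table,
        best_offset=float(best_offset),
        best_length=float(best_length),
        best_accuracy=best_acc,
    )


def sweep_bands(
    epochs: EpochSet,
    fft_bands: Sequence[tuple[float, float]] = (),
    ar_bands: Sequence[tuple[float, float]] = (),
    cfg: PipelineConfig | None = None,
    k: int | None = None,
    seed: int = 0,
    model_factory: ModelFactory | None = None,
) -> pd.DataFrame:
    """Mean CV accuracy per candidate frequency band.

    FFT candidate bands are swept with the AR sub-bands held at their
    configured values; AR candidate bands are swept with the FFT band held
    at its configured value.  Duplicate candidates are dropped with a
    warning.
    """
    cfg = cfg or PipelineConfig()

    def dedup(bands):
        seen, out = set(), []
        for b in bands:
            key = (float(b[0]), float(b[1]))
            if key in seen:
                warnings.warn(f"duplicate band {key} dropped", UserWarning)
                continue
            seen.add(key)
            out.append(key)
        return out

    rows = []
    for band in dedup(fft_bands):
        cell_cfg = cfg.replace(spectral=type(cfg.spectral)(
            seg_len=cfg.spectral.seg_len, hop=cfg.spectral.hop, bands=[band]
        ))
        rep = kfold_cv(epochs, cell_cfg, k=k, seed=seed, model_factory=model_factory)
        rows.append({"varied": "fft", "band": f"{band[0]:g}-{band[1]:g}",
                     "accuracy": rep.mean_accuracy})
    for band in dedup(ar_bands):
        cell_cfg = cfg.replace(ar=type(cfg.ar)(order=cfg.ar.order, bands=[band]))
        rep = kfold_cv(epochs, cell_cfg, k=k, seed=seed, model_factory=model_factory)
        rows.append({"varied": "ar", "band": f"{band[0]:g}-{band[1]:g}",
                     "accuracy": rep.mean_accuracy})
    return pd.DataFrame(rows)
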
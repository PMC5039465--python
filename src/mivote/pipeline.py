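"""Wiring of the full pipeline: preprocess, extract, select, train, predict.

``extract_features`` turns an :class:`EpochSet` into the combined feature
vector (spectral amplitude/phase averages plus phase-space/AR features);
``fit_pipeline`` additionally runs per-pair SFFS and trains the one-vs-one
voting classifier (or a plain multi-class KNN, which per the baseline
design skips both pairing and selection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mivote.classification import (
    PairModel,
    VotingClassifier,
    make_estimator,
    train_pair,
)
from mivote.config import PipelineConfig
from mivote.dataset_io import ClassLabel, EpochSet
from mivote.feature_matrix import FeatureMatrix
from mivote.preprocessing import (
    FilterSpec,
    LaplacianSpec,
    WindowSpec,
    extract_window,
    surface_laplacian,
)
from mivote.psr_ar import ArSpec, EmbeddingSpec, psr_ar_features
from mivote.selection import CLASS_PAIRS, SelectionResult, pairwise_select
from mivote.spectral import SpectralSpec, spectral_features

__all__ = ["extract_features", "fit_pipeline", "fit_on_features", "FittedPipeline"]


def _laplacian_spec(cfg: PipelineConfig) -> LaplacianSpec:
    kwargs = {"centers": list(cfg.laplacian.centers)}
    if cfg.laplacian.neighbors is not None:
        kwargs["neighbors"] = dict(cfg.laplacian.neighbors)
    return LaplacianSpec(**kwargs)


def _band_filters(cfg: PipelineConfig) -> list[FilterSpec]:
    return [
        FilterSpec(
            band=tuple(band),
            order=cfg.filter.order,
            passband_ripple_db=cfg.filter.ripple_db,
            stopband_atten_db=cfg.filter.atten_db,
            application=cfg.filter.application,
        )
        for band in cfg.ar.bands
    ]


def extract_features(epochs: EpochSet, cfg: PipelineConfig | None = None) -> FeatureMatrix:
    """Laplacian -> analysis window -> spectral + phase-space/AR features."""
    cfg = cfg or PipelineConfig()
    lap = surface_laplacian(epochs, _laplacian_spec(cfg))
    win = extract_window(
        lap,
        WindowSpec(
            offset=cfg.window.offset,
            length=cfg.window.length,
            anchor=cfg.window.anchor,
        ),
    )
    fm_spec = spectral_features(
        win,
        SpectralSpec(
            seg_len=cfg.spectral.seg_len,
            hop=cfg.spectral.hop,
            bands=[tuple(b) for b in cfg.spectral.bands],
        ),
    )
    fm_ar = psr_ar_features(
        win,
        EmbeddingSpec(m=cfg.psr.m, tau=cfg.psr.tau),
        ArSpec(p=cfg.ar.order, bands=[tuple(b) for b in cfg.ar.bands]),
        filters=_band_filters(cfg),
    )
    return FeatureMatrix.hstack([fm_spec, fm_ar])


@dataclass
class FittedPipeline:
    """A trained pipeline: config, per-pair selections and the classifier."""

    cfg: PipelineConfig
    voting: VotingClassifier | None = None
    knn: object | None = None
    selections: dict[tuple[str, str], SelectionResult] | None = None

    def predict(self, epochs: EpochSet) -> list[ClassLabel]:
        fm = extract_features(epochs, self.cfg)
        return self.predict_features(fm)

    def predict_features(self, fm: FeatureMatrix) -> list[ClassLabel]:
        if self.voting is not None:
            return self.voting.predict(fm.values)
        pred = self.knn.predict(fm.values)
        return [ClassLabel(p) for p in pred]

    def pair_scores(self, fm: FeatureMatrix) -> dict[tuple[str, str], np.ndarray]:
        """Continuous per-pair decision scores for ROC analysis."""
        if self.voting is None:
            raise ValueError("pair scores only exist for the one-vs-one scheme")
        return {
            pair: model.decision_scores(fm.values)
            for pair, model in self.voting.models.items()
        }


def fit_pipeline(
    train_epochs: EpochSet,
    cfg: PipelineConfig | None = None,
    seed: int | None = None,
) -> FittedPipeline:
    """Train on labelled epochs; returns a predictor for unseen epochs.

    For ``clf.type`` of ``multi-lda``/``multi-svm``: per-pair SFFS (when
    enabled) then three binary classifiers combined by the vote table.
    For ``knn``: one multi-class k-NN on the full feature vector.
    """
    cfg = cfg or PipelineConfig()
    fm = extract_features(train_epochs, cfg)
    return fit_on_features(fm, cfg, seed=seed)


def fit_on_features(
    fm: FeatureMatrix,
    cfg: PipelineConfig | None = None,
    seed: int | None = None,
) -> FittedPipeline:
    """Selection + classifier training on an already-extracted feature matrix.

    Feature extraction is trial-local, so cross-validation extracts once
    and calls this per training fold without any train/test leakage.
    """
    cfg = cfg or PipelineConfig()
    if seed is None:
        seed = cfg.seed

    if cfg.clf.type == "knn":
        knn = make_estimator("knn", knn_k=cfg.clf.knn_k)
        knn.fit(fm.values, fm.label_array())
        fitted = FittedPipeline(cfg=cfg)
        fitted.knn = knn
        return fitted

    learner = {"multi-lda": "lda", "multi-svm": "svm"}.get(cfg.clf.type)
    if learner is None:
        raise ValueError(
            f"unknown clf.type {cfg.clf.type!r}; expected multi-lda, multi-svm or knn"
        )

    selections: dict[tuple[str, str], SelectionResult] | None = None
    if cfg.sffs.enabled:
        selections = pairwise_select(
            fm,
            estimator_factory=lambda: make_estimator(
                learner, svm_c=cfg.clf.svm_c, knn_k=cfg.clf.knn_k
            ),
            inner_folds=cfg.sffs.inner_folds,
            max_features=cfg.sffs.max_features,
            seed=seed,
        )

    models: dict[tuple[str, str], PairModel] = {}
    for pair in CLASS_PAIRS:
        idx = None
        if selections is not None and selections[pair].selected:
            idx = selections[pair].selected
        models[pair] = train_pair(
            fm,
            pair,
            learner=learner,
            feature_indices=idx,
            svm_c=cfg.clf.svm_c,
            knn_k=cfg.clf.knn_k,
        )
    return FittedPipeline(cfg=cfg, voting=VotingClassifier(models), selections=selections)
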
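"""Metrics, cross-validation protocol, ROC and parameter sweeps."""

import hashlib
import pickle

import numpy as np
import pytest

from mivote import (
    ClassLabel,
    SynthConfig,
    accuracy,
    generate_session,
    itr,
    kappa,
    kfold_cv,
    roc_analysis,
    sweep_bands,
    sweep_offset_window,
)
from mivote.config import ArConfig, ClfConfig, PipelineConfig, SffsConfig
from mivote.evaluation import DEFAULT_OFFSETS, DEFAULT_WINDOW_LENGTHS, ItrParams
from mivote.pipeline import fit_on_features


class _StubModel:
    def __init__(self, fn):
        self.fn = fn

    def predict_features(self, fm):
        return self.fn(fm)


def oracle_factory(train_fm, cfg, seed):
    """Perfect classifier stub: echoes the true labels."""
    return _StubModel(lambda fm: [ClassLabel(lab) for lab in fm.labels])


def majority_factory(train_fm, cfg, seed):
    """Majority-class dummy: constant prediction of the modal training label."""
    labs, counts = np.unique(train_fm.label_array(), return_counts=True)
    winner = labs[np.argmax(counts)]  # ties -> lexicographically first
    return _StubModel(lambda fm: [ClassLabel(winner)] * fm.n_trials)


class TestAccuracy:
    def test_all_correct(self):
        assert accuracy(["LH"] * 24, ["LH"] * 24) == 100.0

    def test_twenty_of_twentyfour(self):
        preds = ["LH"] * 20 + ["RH"] * 4
        assert accuracy(preds, ["LH"] * 24) == pytest.approx(83.333, abs=1e-3)

    def test_all_none_rejects_score_zero(self):
        preds = [ClassLabel.NONE] * 10
        assert accuracy(preds, ["LH"] * 10) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy([], [])

    def test_none_in_truth_rejected(self):
        with pytest.raises(ValueError):
            accuracy(["LH"], [ClassLabel.NONE])


class TestKappa:
    def test_perfect_agreement(self):
        assert kappa(1.0) == pytest.approx(1.0)

    def test_chance_level(self):
        assert kappa(1.0 / 3.0) == pytest.approx(0.0, abs=1e-12)

    def test_published_style_value(self):
        assert kappa(0.8606) == pytest.approx(0.7909, abs=1e-4)

    def test_degenerate_chance_rejected(self):
        with pytest.raises(ValueError):
            kappa(0.9, chance=1.0)


class TestItr:
    def test_perfect_accuracy_is_l_log2_n(self):
        assert itr(ItrParams(L=30, p=1.0, N_targets=3)) == pytest.approx(
            30 * np.log2(3), abs=1e-9
        )

    def test_chance_three_targets_is_zero(self):
        assert itr(ItrParams(L=12, p=1.0 / 3.0, N_targets=3)) == pytest.approx(0.0, abs=1e-12)

    def test_binary_chance_is_zero(self):
        assert itr(ItrParams(L=7, p=0.5, N_targets=2)) == pytest.approx(0.0, abs=1e-12)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            ItrParams(L=0, p=0.5)
        with pytest.raises(ValueError):
            ItrParams(L=10, p=1.5)


@pytest.fixture(scope="module")
def balanced_216():
    """72 trials per class: the fold arithmetic of a 216-trial session."""
    return generate_session(SynthConfig(n_trials_per_class=72, erd_depth=0.8, seed=0))


class TestKfold:
    def test_nine_fold_split_sizes(self, balanced_216):
        sizes = []

        def factory(train_fm, cfg, seed):
            sizes.append(train_fm.n_trials)
            return oracle_factory(train_fm, cfg, seed)

        rep = kfold_cv(balanced_216, k=9, seed=0, model_factory=factory)
        assert all(n == 192 for n in sizes)  # 192 training trials per fold
        assert rep.k == 9
        # 24 held-out trials per fold -> confusion totals 216
        assert int(rep.confusion.values.sum()) == 216

    def test_oracle_stub_hits_ceiling(self, balanced_216):
        rep = kfold_cv(balanced_216, k=9, seed=0, model_factory=oracle_factory)
        assert rep.mean_accuracy == 100.0
        assert rep.kappa == pytest.approx(1.0)

    def test_majority_dummy_sits_at_chance(self, balanced_216):
        rep = kfold_cv(balanced_216, k=9, seed=0, model_factory=majority_factory)
        assert rep.mean_accuracy == pytest.approx(100.0 / 3.0, abs=1e-9)
        assert rep.kappa == pytest.approx(0.0, abs=1e-9)

    def test_indivisible_fold_count_rejected(self):
        ep = generate_session(SynthConfig(n_trials_per_class=10, seed=1))
        with pytest.raises(ValueError, match="compatible"):
            kfold_cv(ep, k=9)

    def test_k_larger_than_class_count_rejected(self):
        ep = generate_session(SynthConfig(n_trials_per_class=4, seed=1))
        with pytest.raises(ValueError, match="k="):
            kfold_cv(ep, k=6)

    def test_fitted_model_independent_of_test_labels(self, strong_erd_session):
        # the fit sees only the training fold, so corrupting held-out labels
        # cannot change the fitted model state
        from mivote.pipeline import extract_features
        from mivote import FeatureMatrix

        cfg = PipelineConfig(sffs=SffsConfig(enabled=False))
        fm = extract_features(strong_erd_session, cfg)
        train_idx = np.arange(0, fm.n_trials, 2)
        train_fm = FeatureMatrix(
            values=fm.values[train_idx],
            feature_names=list(fm.feature_names),
            labels=[fm.labels[i] for i in train_idx],
        )

        def state_hash():
            model = fit_on_features(train_fm, cfg, seed=0)
            blob = pickle.dumps(
                [model.voting.models[p].estimator.coef_ for p in model.voting.models]
            )
            return hashlib.sha256(blob).hexdigest()

        h1 = state_hash()
        # "corrupt" every label outside the training fold
        for i in range(fm.n_trials):
            if i not in train_idx:
                fm.labels[i] = "F"
        h2 = state_hash()
        assert h1 == h2


class TestRoc:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(20), np.ones(20)]
        truth = ["LH"] * 20 + ["RH"] * 20
        assert roc_analysis(scores, truth, positive_label="RH").auc == 1.0

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=2000)
        truth = rng.permutation(["LH"] * 1000 + ["RH"] * 1000)
        assert 0.45 <= roc_analysis(scores, truth).auc <= 0.55

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=300)
        truth = ["LH" if s + rng.normal() < 0.3 else "RH" for s in scores]
        a = roc_analysis(scores, truth, positive_label="RH").auc
        b = roc_analysis(np.exp(3 * scores), truth, positive_label="RH").auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            roc_analysis(np.arange(5.0), ["LH"] * 5)


@pytest.fixture(scope="module")
def small_session():
    return generate_session(SynthConfig(n_trials_per_class=4, erd_depth=0.8, seed=2))


class TestSweeps:
    def test_default_grid_enumerates_121_cells(self, small_session):
        res = sweep_offset_window(small_session, k=2, seed=0, model_factory=oracle_factory)
        assert res.n_cells == 121
        assert len(DEFAULT_OFFSETS) == len(DEFAULT_WINDOW_LENGTHS) == 11

    def test_single_cell_equals_direct_cv(self, small_session):
        res = sweep_offset_window(
            small_session,
            offsets=[0.0],
            window_lengths=[2.0],
            k=2,
            seed=0,
            model_factory=majority_factory,
        )
        direct = kfold_cv(small_session, k=2, seed=0, model_factory=majority_factory)
        assert res.best_accuracy == pytest.approx(direct.mean_accuracy)
        assert res.n_cells == 1

    def test_invalid_cells_marked_nan(self, small_session):
        # a 3.2-s window violates the window-length contract -> NaN, not skip
        res = sweep_offset_window(
            small_session,
            offsets=[0.0],
            window_lengths=[2.0, 3.2],
            k=2,
            seed=0,
            model_factory=oracle_factory,
        )
        assert np.isnan(res.table.loc[3.2, 0.0])
        assert res.best_length == 2.0

    def test_band_sweep_prefers_informative_band(self):
        # rhythms live in ~9-12 and ~19-25 Hz; a 35-45 Hz band sees noise only
        ep = generate_session(SynthConfig(n_trials_per_class=10, erd_depth=0.9, seed=6))
        cfg = PipelineConfig(
            sffs=SffsConfig(enabled=False),
            ar=ArConfig(bands=[(35.0, 45.0)]),
        )
        table = sweep_bands(
            ep,
            fft_bands=[(8.0, 14.0), (35.0, 45.0)],
            cfg=cfg,
            k=3,
            seed=0,
        )
        fft_rows = table[table["varied"] == "fft"].set_index("band")["accuracy"]
        assert fft_rows["8-14"] > fft_rows["35-45"]
        assert fft_rows["35-45"] < 60.0  # uninformative band stays near chance

    def test_duplicate_bands_deduplicated_with_warning(self, small_session):
        with pytest.warns(UserWarning, match="duplicate"):
            table = sweep_bands(
                small_session,
                fft_bands=[(8.0, 34.0), (8.0, 34.0)],
                cfg=PipelineConfig(sffs=SffsConfig(enabled=False)),
                k=2,
                seed=0,
                model_factory=majority_factory,
            )
        assert len(table) == 1
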
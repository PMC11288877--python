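"""Decoder training, grid search, imbalance handling and the three regimes."""

import numpy as np
import pandas as pd
import pytest

from errpsim import classify, features as feat
from errpsim.classify import (
    CvConfig,
    ErrPSvmClassifier,
    SvmGrid,
    downsample_majority,
    evaluate_loso,
    evaluate_subject_specific,
    grid_search_train,
    train_generic,
)

TINY_GRID = SvmGrid(cost_values=(1.0,), gamma_values=(0.01,))


def _feature_matrix(rng, n_err=40, n_cor=160, n_feat=16, separation=0.0,
                    subject_id="s"):
    X = np.concatenate([
        rng.normal(separation, 1.0, size=(n_err, n_feat)),
        rng.normal(0.0, 1.0, size=(n_cor, n_feat)),
    ])
    y = np.array(["error"] * n_err + ["correct"] * n_cor)
    perm = rng.permutation(y.size)
    return feat.FeatureMatrix(values=X[perm], window_defs=[(0, 100)] * n_feat,
                              channel_subset=["x"], labels=y[perm],
                              subject_id=subject_id)


class TestDownsampleMajority:
    def test_imbalanced_input_balanced_exactly(self, rng):
        labels = np.array(["correct"] * 960 + ["error"] * 240)
        kept = downsample_majority(labels, rng)
        vals, counts = np.unique(labels[kept], return_counts=True)
        assert dict(zip(vals, counts)) == {"correct": 240, "error": 240}

    def test_balanced_input_kept_entirely(self, rng):
        labels = np.array(["correct", "error"] * 50)
        assert downsample_majority(labels, rng).size == 100

    def test_deterministic_for_fixed_rng(self):
        labels = np.array(["correct"] * 30 + ["error"] * 10)
        a = downsample_majority(labels, np.random.default_rng(3))
        b = downsample_majority(labels, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            downsample_majority(np.array(["error"] * 10), rng)


class TestSvmGrid:
    def test_default_grid_is_13_by_11(self):
        grid = SvmGrid()
        assert len(grid.cost_values) == 13 and len(grid.gamma_values) == 11
        assert len(grid.pairs()) == 143
        assert min(grid.cost_values) == pytest.approx(1e-6)
        assert max(grid.cost_values) == pytest.approx(1e6)
        assert min(grid.gamma_values) == pytest.approx(1e-5)
        assert max(grid.gamma_values) == pytest.approx(1e5)

    def test_reduced_grid_is_7_by_6(self):
        assert len(SvmGrid.reduced()) == 42

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            SvmGrid(cost_values=(0.0, 1.0))


class TestGridSearch:
    def test_separable_data_reaches_perfect_inner_score(self, rng):
        fm = _feature_matrix(rng, n_err=30, n_cor=60, separation=8.0)
        clf = grid_search_train(fm.values, fm.labels,
                                SvmGrid(cost_values=(0.1, 1.0, 10.0),
                                        gamma_values=(0.01, 0.1)),
                                inner_folds=3, rng=rng)
        assert clf.grid_scores_["mean_bacc"].max() == 1.0

    def test_tie_break_prefers_smallest_cost_then_gamma(self, rng):
        fm = _feature_matrix(rng, n_err=30, n_cor=60, separation=8.0)
        clf = grid_search_train(fm.values, fm.labels,
                                SvmGrid(cost_values=(0.1, 1.0, 10.0),
                                        gamma_values=(0.01, 0.1)),
                                inner_folds=3, rng=rng)
        scores = clf.grid_scores_
        best = scores["mean_bacc"].max()
        winners = scores[scores["mean_bacc"] == best]
        first = winners.sort_values(["cost", "gamma"]).iloc[0]
        assert (clf.cost_, clf.gamma_) == (first["cost"], first["gamma"])

    def test_class_weights_are_inverse_frequencies_of_raw_labels(self, rng):
        fm = _feature_matrix(rng, n_err=40, n_cor=160)
        clf = grid_search_train(fm.values, fm.labels, TINY_GRID, 2, rng)
        assert clf.class_weights_["error"] == pytest.approx(200 / (2 * 40))
        assert clf.class_weights_["correct"] == pytest.approx(200 / (2 * 160))
        ratio = clf.class_weights_["error"] / clf.class_weights_["correct"]
        assert ratio == pytest.approx(160 / 40)

    def test_degenerate_training_set_rejected(self, rng):
        X = rng.normal(size=(5, 4))
        with pytest.raises(ValueError):
            ErrPSvmClassifier(grid=TINY_GRID).fit(X, np.array(["error"] * 5))


class TestLeakage:
    def test_training_statistics_never_see_test_trials(self, rng, monkeypatch):
        """Audit: every normalizer and SVM fit inside the CV must see fewer
        trials than the full dataset (training portions only)."""
        fit_sizes = []
        orig_norm_fit = feat.FeatureNormalizer.fit

        def spy_norm(self, X, y=None):
            fit_sizes.append(np.asarray(X).shape[0])
            return orig_norm_fit(self, X, y)

        monkeypatch.setattr(feat.FeatureNormalizer, "fit", spy_norm)
        from sklearn.svm import SVC

        svc_sizes = []
        orig_svc_fit = SVC.fit

        def spy_svc(self, X, y, sample_weight=None):
            svc_sizes.append(np.asarray(X).shape[0])
            return orig_svc_fit(self, X, y, sample_weight)

        monkeypatch.setattr(SVC, "fit", spy_svc)

        fm = _feature_matrix(rng, n_err=30, n_cor=90, separation=2.0)
        n_total = fm.values.shape[0]
        cfg = CvConfig(grid=TINY_GRID, inner_folds=2, n_folds=4, n_repeats=1)
        evaluate_subject_specific(fm, cfg)
        assert fit_sizes and svc_sizes
        assert max(fit_sizes) < n_total
        assert max(svc_sizes) < n_total

    def test_normalizer_fit_on_downsampled_training_set(self, rng):
        fm = _feature_matrix(rng, n_err=20, n_cor=80)
        clf = ErrPSvmClassifier(grid=TINY_GRID, inner_folds=2, random_state=5)
        clf.fit(fm.values, fm.labels)
        # final normalizer saw a balanced subset: 2 * 20 trials
        assert clf.svc_.shape_fit_[0] == 40


class TestSubjectSpecific:
    def test_shuffled_labels_score_chance(self):
        rng = np.random.default_rng(0)
        fm = _feature_matrix(rng, n_err=60, n_cor=240, separation=0.0)
        cfg = CvConfig(grid=TINY_GRID, inner_folds=2, n_folds=5, n_repeats=2)
        res = evaluate_subject_specific(fm, cfg)
        assert res.mean_bacc == pytest.approx(0.5, abs=0.05)

    def test_separable_subject_scores_high(self, rng):
        fm = _feature_matrix(rng, n_err=40, n_cor=160, separation=6.0)
        cfg = CvConfig(grid=SvmGrid(cost_values=(1.0, 10.0), gamma_values=(0.01,)),
                       inner_folds=2, n_folds=5, n_repeats=1)
        res = evaluate_subject_specific(fm, cfg)
        assert res.mean_bacc > 0.95

    def test_fold_bacc_is_mean_of_rates(self, rng):
        fm = _feature_matrix(rng, n_err=40, n_cor=80, separation=2.0)
        cfg = CvConfig(grid=TINY_GRID, inner_folds=2, n_folds=4, n_repeats=1)
        res = evaluate_subject_specific(fm, cfg)
        assert np.allclose(res.frame["bacc"],
                           (res.frame["tpr"] + res.frame["tnr"]) / 2)
        assert len(res.frame) == 4

    def test_too_many_folds_advises_fewer(self, rng):
        fm = _feature_matrix(rng, n_err=5, n_cor=50)
        with pytest.raises(ValueError, match="fewer folds"):
            evaluate_subject_specific(fm, CvConfig(grid=TINY_GRID, n_folds=10))


class TestLoso:
    def test_one_row_per_subject_and_holdout_isolation(self, rng):
        subs = [_feature_matrix(rng, n_err=20, n_cor=60, separation=3.0,
                                subject_id=f"s{i}") for i in range(3)]
        cfg = CvConfig(grid=TINY_GRID, inner_folds=2)
        df = evaluate_loso(subs, cfg)
        assert list(df["subject"]) == ["s0", "s1", "s2"]
        assert ((df["bacc"] >= 0) & (df["bacc"] <= 1)).all()

    def test_identical_subjects_transfer_perfectly_when_separable(self, rng):
        base = _feature_matrix(rng, n_err=20, n_cor=60, separation=6.0)
        subs = [base, feat.FeatureMatrix(values=base.values.copy(),
                                         window_defs=base.window_defs,
                                         channel_subset=base.channel_subset,
                                         labels=base.labels.copy(),
                                         subject_id="twin")]
        df = evaluate_loso(subs, CvConfig(grid=TINY_GRID, inner_folds=2))
        assert (df["bacc"] > 0.95).all()

    def test_single_subject_rejected(self, rng):
        with pytest.raises(ValueError):
            evaluate_loso([_feature_matrix(rng)], CvConfig(grid=TINY_GRID))


class TestGeneric:
    def test_frozen_model_is_deterministic_and_lists_provenance(self, rng):
        subs = [_feature_matrix(rng, separation=3.0, subject_id=f"train-{i}")
                for i in range(3)]
        model = train_generic(subs, CvConfig(grid=TINY_GRID, inner_folds=2))
        assert model.training_subjects == ["train-0", "train-1", "train-2"]
        test = _feature_matrix(rng, separation=3.0)
        a = model.predict(test)
        b = model.predict(test)
        assert np.array_equal(a, b)
        assert model.kernel == "radial"

    def test_feature_mismatch_on_apply_rejected(self, rng):
        subs = [_feature_matrix(rng, separation=3.0) for _ in range(2)]
        model = train_generic(subs, CvConfig(grid=TINY_GRID, inner_folds=2))
        with pytest.raises(ValueError, match="mismatch"):
            model.predict(rng.normal(size=(10, 5)))

    def test_permuted_validation_labels_score_chance(self):
        from errpsim.evaluate import balanced_accuracy

        rng = np.random.default_rng(1)
        subs = [_feature_matrix(rng, separation=3.0, subject_id=f"t{i}")
                for i in range(3)]
        model = train_generic(subs, CvConfig(grid=TINY_GRID, inner_folds=2))
        val = _feature_matrix(rng, n_err=100, n_cor=400, separation=3.0)
        pred = model.predict(val)
        baccs = [balanced_accuracy(rng.permutation(val.labels), pred).bacc
                 for _ in range(50)]
        assert np.mean(baccs) == pytest.approx(0.5, abs=0.03)

    def test_model_round_trip(self, rng, tmp_path):
        subs = [_feature_matrix(rng, separation=3.0) for _ in range(2)]
        model = train_generic(subs, CvConfig(grid=TINY_GRID, inner_folds=2))
        p = tmp_path / "model.bin"
        model.save(p)
        back = classify.TrainedModel.load(p)
        test = _feature_matrix(rng)
        assert np.array_equal(back.predict(test), model.predict(test))
        assert (back.cost, back.gamma) == (model.cost, model.gamma)
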
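import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from enhancerstack.base_forest import ForestConfig, train_base
from enhancerstack.features import FeatureMatrix, LabeledDataset
from enhancerstack.meta_svm import (
    MetaDataset,
    SvmConfig,
    balanced_error_rate,
    build_meta_features,
    grid_search_svm,
    predict_meta,
    rbf_kernel,
)


def trained_base(seed, n=200, fscore_feature_shift=1.0):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.3).astype(int)
    X = rng.random((n, 2))
    X[:, 0] += fscore_feature_shift * y
    ds = LabeledDataset(
        FeatureMatrix([f"w{i}" for i in range(n)], ["a", "b"], X), y, f"t{seed}"
    )
    return train_base(ds, ForestConfig(n_trees=30, seed=seed))


def separable_meta(rng, n=200, margin=0.3):
    y = (rng.random(n) < 0.4).astype(int)
    X = rng.random((n, 2)) * 0.2
    X[y == 1] += 0.5 + margin
    return MetaDataset(np.clip(X, 0, 1), ["t1", "t2"], y)


class TestBuildMetaFeatures:
    def test_confidence_times_fscore_arithmetic(self):
        m1, m2 = trained_base(1), trained_base(2)
        X = np.random.default_rng(3).random((50, 2))
        meta = build_meta_features([m1, m2], X)
        from enhancerstack.base_forest import confidence_scores

        expected = np.column_stack(
            [confidence_scores(m1, X) * m1.heldout_fscore, confidence_scores(m2, X) * m2.heldout_fscore]
        )
        np.testing.assert_allclose(meta.meta_features, expected)
        assert meta.base_names == [m1.tissue, m2.tissue]

    def test_column_bounded_by_fscore(self):
        models = [trained_base(4), trained_base(5)]
        X = np.random.default_rng(6).random((80, 2))
        meta = build_meta_features(models, X)
        for j, m in enumerate(models):
            assert meta.meta_features[:, j].max() <= m.heldout_fscore + 1e-12

    def test_zero_fscore_annihilates_column(self):
        m1, m2 = trained_base(7), trained_base(8)
        m2.heldout_fscore = 0.0
        meta = build_meta_features([m1, m2], np.random.default_rng(9).random((30, 2)))
        assert not meta.meta_features[:, 1].any()

    def test_single_model_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_meta_features([trained_base(10)], np.zeros((5, 2)))


class TestRbfKernel:
    def test_self_similarity_is_one(self):
        x = np.array([0.3, -1.2, 5.0])
        assert rbf_kernel(x, x, gamma=7.0) == 1.0

    def test_unit_distance_value(self):
        assert rbf_kernel([0.0], [1.0], gamma=1.0) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a, b = rng.normal(size=4), rng.normal(size=4)
            assert rbf_kernel(a, b, 2.5) == rbf_kernel(b, a, 2.5)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            rbf_kernel([1.0, 2.0], [1.0], gamma=1.0)

    def test_scale_gamma_invariance(self):
        """Scaling inputs by c and gamma by 1/c^2 leaves the kernel matrix
        unchanged."""
        rng = np.random.default_rng(12)
        X = rng.random((6, 3))
        c = 3.7
        for i in range(6):
            for j in range(6):
                assert rbf_kernel(X[i], X[j], 8.0) == pytest.approx(
                    rbf_kernel(c * X[i], c * X[j], 8.0 / c**2), abs=1e-12
                )


class TestBalancedErrorRate:
    def test_perfect_predictions(self):
        assert balanced_error_rate([1, 0, 1, 0], [1, 0, 1, 0]) == 0.0

    def test_degenerate_all_positive_predictor(self):
        assert balanced_error_rate([1, 1, 0, 0, 0], [1, 1, 1, 1, 1]) == 0.5

    def test_hand_counted_confusion(self):
        # TP=3, FN=1, TN=2, FP=2 -> 1 - (0.75 + 0.5)/2
        y = [1, 1, 1, 1, 0, 0, 0, 0]
        p = [1, 1, 1, 0, 1, 1, 0, 0]
        assert balanced_error_rate(y, p) == pytest.approx(0.375)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            balanced_error_rate([1, 1], [1, 0])


class TestGridSearch:
    def test_separable_meta_reaches_zero_cv_ber(self):
        meta = separable_meta(np.random.default_rng(13))
        cfg = SvmConfig(C_grid=(2, 8), gamma_grid=(2, 20), n_folds=5, seed=0)
        model = grid_search_svm(meta, cfg)
        assert model.cv_balanced_error == 0.0
        assert model.chosen_C in cfg.C_grid and model.chosen_gamma in cfg.gamma_grid

    def test_matches_exhaustive_recomputation_on_3x3_grid(self):
        """Chosen pair and BER surface equal an independent loop over the
        same seeded folds."""
        rng = np.random.default_rng(14)
        y = (rng.random(200) < 0.35).astype(int)
        X = rng.random((200, 3)) * 0.5
        X[y == 1, 0] += 0.3 * rng.random((y == 1).sum())  # partly separable
        meta = MetaDataset(X, ["a", "b", "c"], y)
        cfg = SvmConfig(C_grid=(2, 10, 50), gamma_grid=(2, 50, 200), n_folds=10, seed=5)
        model = grid_search_svm(meta, cfg)

        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=5)
        folds = list(skf.split(X, y))
        oracle = {}
        for C in cfg.C_grid:
            for g in cfg.gamma_grid:
                bers = []
                for tr, va in folds:
                    clf = SVC(C=C, gamma=g, kernel="rbf", tol=1e-3).fit(X[tr], y[tr])
                    pred = clf.predict(X[va])
                    yv = y[va]
                    sens = ((yv == 1) & (pred == 1)).sum() / (yv == 1).sum()
                    spec = ((yv == 0) & (pred == 0)).sum() / (yv == 0).sum()
                    bers.append(1 - (sens + spec) / 2)
                oracle[(C, g)] = np.mean(bers)
        best_oracle = min(oracle, key=lambda k: (oracle[k], k[0], k[1]))
        assert (model.chosen_C, model.chosen_gamma) == best_oracle
        assert model.cv_balanced_error == pytest.approx(oracle[best_oracle], abs=1e-12)
        surface_oracle = np.array(
            [[oracle[(C, g)] for g in cfg.gamma_grid] for C in cfg.C_grid]
        )
        np.testing.assert_allclose(model.cv_surface, surface_oracle, atol=1e-12)

    def test_cv_folds_partition_the_dataset(self):
        y = np.array([0, 1] * 25)
        X = np.random.default_rng(15).random((50, 2))
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        seen = np.concatenate([va for _, va in skf.split(X, y)])
        assert sorted(seen.tolist()) == list(range(50))

    def test_grid_zero_rejected_and_fold_limits(self):
        with pytest.raises(ValueError, match="positive"):
            SvmConfig(C_grid=(0, 2), gamma_grid=(2,))
        meta = separable_meta(np.random.default_rng(16), n=12)
        with pytest.raises(ValueError):
            grid_search_svm(meta, SvmConfig(C_grid=(2,), gamma_grid=(2,), n_folds=10))


class TestPredictMeta:
    def test_training_accuracy_on_separable(self):
        meta = separable_meta(np.random.default_rng(17))
        model = grid_search_svm(meta, SvmConfig(C_grid=(2, 8), gamma_grid=(2, 20), n_folds=5))
        scores, labels = predict_meta(model, meta)
        np.testing.assert_array_equal(labels, meta.labels)

    def test_label_is_sign_of_score(self):
        meta = separable_meta(np.random.default_rng(18))
        model = grid_search_svm(meta, SvmConfig(C_grid=(2,), gamma_grid=(2,), n_folds=5))
        scores, labels = predict_meta(model, meta.meta_features + 0.05)
        np.testing.assert_array_equal(labels, (scores > 0).astype(int))

    def test_decision_matches_dual_form_oracle(self):
        """Decision values equal sum_i alpha_i y_i k(sv_i, x) + b computed
        from the stored dual coefficients."""
        rng = np.random.default_rng(19)
        meta = separable_meta(rng, n=20)
        model = grid_search_svm(meta, SvmConfig(C_grid=(4,), gamma_grid=(8,), n_folds=2))
        X_new = rng.random((7, 2))
        scores, _ = predict_meta(model, X_new)
        svm = model.svm
        for i, x in enumerate(X_new):
            dual = sum(
                coef * rbf_kernel(sv, x, model.chosen_gamma)
                for coef, sv in zip(svm.dual_coef_[0], svm.support_vectors_)
            )
            assert scores[i] == pytest.approx(dual + svm.intercept_[0], abs=1e-9)

    def test_column_mismatch_rejected(self):
        meta = separable_meta(np.random.default_rng(20))
        model = grid_search_svm(meta, SvmConfig(C_grid=(2,), gamma_grid=(2,), n_folds=5))
        wrong = MetaDataset(meta.meta_features, ["x", "y"])
        with pytest.raises(ValueError, match="do not match"):
            predict_meta(model, wrong)
        with pytest.raises(ValueError, match="columns"):
            predict_meta(model, np.zeros((3, 5)))
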
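"""Unit tests for the per-motif logistic layer and its training machinery."""

import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from m6aread.classifier import (
    ModelBundle,
    MotifLogisticClassifier,
    MotifModel,
    balance_classes,
    cross_validate_auc,
    log_loss_binary,
    normalize_features,
    train_motif_model,
)
from m6aread.motifs import SUPPORTED_MOTIFS
from m6aread.synthetic import gen_training_set
from tests.conftest import make_dist


class TestNormalize:
    def test_divides_by_max_abs(self):
        np.testing.assert_allclose(
            normalize_features(np.array([2.0, -4.0, 0.0])), [0.5, -1.0, 0.0]
        )

    def test_all_zero_vector_unchanged(self):
        np.testing.assert_array_equal(normalize_features(np.zeros(5)), np.zeros(5))

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 6)) * 10
        once = normalize_features(X)
        np.testing.assert_allclose(normalize_features(once), once)

    @pytest.mark.parametrize("bad", [np.nan, np.inf, -np.inf])
    def test_rejects_non_finite(self, bad):
        with pytest.raises(ValueError, match="finite"):
            normalize_features(np.array([1.0, bad]))


class TestPredict:
    def test_zero_weights_give_half(self):
        m = MotifModel("GGACT", np.zeros(4), 0.0)
        assert m.predict(np.array([0.3, -0.2, 1.0, 0.5])) == 0.5

    def test_logit_ln3_gives_three_quarters(self):
        # w.x + b = ln 3 on an already-normalized vector
        x = np.array([1.0, 0.0, 0.0])
        m = MotifModel("GGACT", np.array([math.log(3.0), 0.0, 0.0]), 0.0)
        assert m.predict(x) == pytest.approx(0.75, abs=1e-12)

    def test_matches_dot_product_sigmoid_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            d = rng.integers(2, 20)
            w, b = rng.normal(size=d), rng.normal()
            x = normalize_features(rng.normal(size=d))
            expected = 1.0 / (1.0 + math.exp(-(float(np.dot(w, x)) + b)))
            got = MotifModel("GGACT", w, b).predict(x, normalize=False)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        m = MotifModel("GGACT", np.zeros(4), 0.0)
        with pytest.raises(ValueError, match="dimension"):
            m.predict(np.zeros(5))

    def test_bias_shift_moves_logit_exactly(self):
        rng = np.random.default_rng(4)
        w = rng.normal(size=6)
        X = normalize_features(rng.normal(size=(10, 6)))
        p0 = MotifModel("GGACT", w, 0.0).predict(X, normalize=False)
        p1 = MotifModel("GGACT", w, 1.5).predict(X, normalize=False)
        np.testing.assert_allclose(
            np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0)), 1.5, atol=1e-9
        )


class TestLogLoss:
    def test_single_sample_half(self):
        assert log_loss_binary([1], [0.5]) == pytest.approx(math.log(2.0))

    def test_additive_over_samples(self):
        n = 17
        assert log_loss_binary([1] * n, [0.5] * n) == pytest.approx(n * math.log(2.0))

    def test_perfect_predictions_near_zero(self):
        assert log_loss_binary([0, 1, 1], [0.0, 1.0, 1.0]) < 1e-10

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            log_loss_binary([], [])


class TestBalance:
    def test_subsamples_majority(self):
        X = np.arange(1400 * 2, dtype=float).reshape(1400, 2)
        y = np.array([0] * 1000 + [1] * 400)
        Xb, yb, kept = balance_classes(X, y, seed=0)
        assert (yb == 0).sum() == 400 and (yb == 1).sum() == 400

    def test_balanced_input_unchanged(self):
        X = np.zeros((8, 2))
        y = np.array([0, 1] * 4)
        _, yb, kept = balance_classes(X, y, seed=5)
        np.testing.assert_array_equal(kept, np.arange(8))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 2))
        y = (rng.random(300) < 0.3).astype(int)
        _, _, kept1 = balance_classes(X, y, seed=9)
        _, _, kept2 = balance_classes(X, y, seed=9)
        np.testing.assert_array_equal(kept1, kept2)

    def test_one_class_absent_names_motif(self):
        with pytest.raises(ValueError, match="GGACA"):
            balance_classes(np.zeros((3, 2)), [1, 1, 1], motif="GGACA")


class TestTraining:
    def test_separable_features_reach_perfect_auc(self):
        dist = make_dist(separation=8.0)
        X, y = gen_training_set("GGACT", 1000, dist=dist, seed=0)
        Xv, yv = gen_training_set("GGACT", 500, dist=dist, seed=1)
        model = train_motif_model(X, y, "GGACT", seed=0)
        assert roc_auc_score(yv, model.predict(Xv)) >= 1.0 - 1e-3

    def test_permuted_labels_give_chance_auc(self):
        dist = make_dist(separation=8.0)
        X, y = gen_training_set("GGACT", 1000, dist=dist, seed=2)
        rng = np.random.default_rng(0)
        y_perm = rng.permutation(y)
        Xv, _ = gen_training_set("GGACT", 1000, dist=dist, seed=3)
        yv_perm = rng.permutation(np.repeat([0, 1], 1000))
        model = train_motif_model(X, y_perm, "GGACT", seed=0)
        assert roc_auc_score(yv_perm, model.predict(Xv)) == pytest.approx(0.5, abs=0.05)

    def test_fit_never_worse_than_null_model(self):
        dist = make_dist(separation=1.0)
        X, y = gen_training_set("GGACT", 200, dist=dist, seed=4)
        model = train_motif_model(X, y, "GGACT", seed=0)
        assert log_loss_binary(y, model.predict(X)) <= len(y) * math.log(2.0)

    def test_weights_recover_separation_direction(self):
        dist = make_dist(separation=4.0)
        X, y = gen_training_set("GGACT", 1000, dist=dist, seed=5)
        model = train_motif_model(X, y, "GGACT", seed=0)
        direction = dist.center("MOD") - dist.center("UNM")
        cos = np.dot(model.weights, direction) / (
            np.linalg.norm(model.weights) * np.linalg.norm(direction)
        )
        assert cos >= 0.9

    def test_non_convergence_flagged(self):
        dist = make_dist(separation=2.0)
        X, y = gen_training_set("GGACT", 200, dist=dist, seed=6)
        with pytest.warns(Warning, match="converge"):
            est = MotifLogisticClassifier(motif="GGACT", max_iter=2).fit(X, y)
        assert est.converged_ is False

    def test_training_meta_recorded(self):
        dist = make_dist(separation=4.0)
        X, y = gen_training_set("GGACT", 50, dist=dist, seed=7)
        model = train_motif_model(X, y, "GGACT", seed=42)
        assert model.meta["n_unm"] == 50 and model.meta["n_mod"] == 50
        assert model.meta["seed"] == 42 and model.meta["converged"]


class TestBundle:
    def test_full_bundle_has_six_models(self):
        bundle = ModelBundle(
            MotifModel(m, np.zeros(8), 0.0) for m in SUPPORTED_MOTIFS
        )
        assert len(bundle) == 6 and bundle.is_complete()

    def test_missing_motif_named_in_error(self):
        bundle = ModelBundle([MotifModel("GGACT", np.zeros(8), 0.0)])
        assert not bundle.is_complete()
        with pytest.raises(KeyError, match="TGACT"):
            bundle["TGACT"]

    def test_rna_alphabet_lookup(self):
        bundle = ModelBundle([MotifModel("GGACT", np.zeros(8), 0.0)])
        assert bundle["GGACU"].motif == "GGACT"


class TestCrossValidation:
    def test_perfectly_separable_folds_all_one(self):
        X, y = gen_training_set("GGACT", 400, dist=make_dist(separation=10.0), seed=8)
        cv = cross_validate_auc(X, y, k=4, seed=0)
        assert all(a == pytest.approx(1.0, abs=1e-6) for a in cv.fold_aucs)
        assert cv.half_range == pytest.approx(0.0, abs=1e-6)

    def test_k2_and_k4_agree(self):
        X, y = gen_training_set("GGACT", 1500, dist=make_dist(separation=2.7), seed=9)
        cv2 = cross_validate_auc(X, y, k=2, seed=0)
        cv4 = cross_validate_auc(X, y, k=4, seed=0)
        assert cv2.mean_auc == pytest.approx(cv4.mean_auc, abs=0.02)

    def test_single_class_fold_skipped_with_warning(self):
        X = np.random.default_rng(0).normal(size=(40, 3))
        y = np.array([1, 1, 1] + [0] * 37)
        with pytest.warns(UserWarning, match="skipped"):
            cv = cross_validate_auc(X, y, k=4, seed=1)
        assert cv.n_folds_skipped >= 1
        assert len(cv.fold_aucs) + cv.n_folds_skipped == 4

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            cross_validate_auc(np.zeros((4, 2)), [0, 1, 0, 1], k=1)
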
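"""Classifier training: Rprop mechanics, MLP selection, SVM contracts."""

import numpy as np
import pytest

from icamam import classify as cl
from icamam.ica_features import FeatureMatrix
from tests_support import COARSE_C_EXPS, COARSE_GAMMA_EXPS, FAST_RPROP


def blobs(n_per_side, sep, seed, q=2):
    """Two Gaussian blobs separated by `sep` along the first axis."""
    rng = np.random.default_rng(seed)
    X0 = rng.standard_normal((n_per_side, q))
    X1 = rng.standard_normal((n_per_side, q))
    X1[:, 0] += sep
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n_per_side, int), np.ones(n_per_side, int)]
    meta = np.array(["normal"] * n_per_side + ["malignant"] * n_per_side)
    return FeatureMatrix(X=X, y=y, pathology=meta,
                         site=np.array(["s"] * 2 * n_per_side))


def split_for(F, seed=0):
    return cl.LearningSplit.random(F.y, test_fraction=0.25,
                                   val_fraction=0.2, seed=seed)


class TestRpropCore:
    @pytest.mark.parametrize("seed", range(3))
    def test_quadratic_converges(self, seed):
        """Batch Rprop with backtracking minimizes a convex quadratic to
        machine-level gradient norm within 200 epochs."""
        A = np.array([[3.0, 1.0], [1.0, 2.0]])
        w0 = np.random.default_rng(seed).uniform(-5, 5, 2)
        cfg = cl.RpropConfig(delta_min=1e-12, max_epochs=200)
        w = cl.rprop_minimize(lambda w: A @ w, w0, cfg, max_epochs=200)
        assert np.linalg.norm(A @ w) < 1e-6

    def test_config_validation(self):
        with pytest.raises(ValueError):
            cl.RpropConfig(eta_plus=0.9)
        with pytest.raises(ValueError):
            cl.RpropConfig(delta0=100.0)


class TestTrainMLP:
    def test_separable_blobs_high_validation_success(self):
        F = blobs(200, 8.0, seed=1)
        split = split_for(F)
        model, trace = cl.train_mlp(F, split, H=10, cfg=FAST_RPROP, seed=0)
        assert trace["val_success"].max() >= 99.0
        # early stopping keeps the best validation weights
        scores = model.scores(F.X[split.val])
        success = 100 * np.mean((scores > 0.5) == (F.y[split.val] == 1))
        assert success == trace["val_success"].max()

    def test_zero_epochs_returns_initial_model(self):
        F = blobs(50, 2.0, seed=2)
        cfg = cl.RpropConfig(max_epochs=0)
        model, trace = cl.train_mlp(F, split_for(F), H=5, cfg=cfg, seed=3)
        assert len(trace) == 0
        assert model.W1.shape == (5, 2)

    def test_deterministic(self):
        F = blobs(60, 3.0, seed=4)
        split = split_for(F)
        m1, _ = cl.train_mlp(F, split, H=8, cfg=FAST_RPROP, seed=9)
        m2, _ = cl.train_mlp(F, split, H=8, cfg=FAST_RPROP, seed=9)
        np.testing.assert_array_equal(m1.W1, m2.W1)
        np.testing.assert_array_equal(m1.w2, m2.w2)

    def test_training_error_decreases(self):
        F = blobs(100, 4.0, seed=5)
        _, trace = cl.train_mlp(F, split_for(F), H=10, cfg=FAST_RPROP, seed=1)
        assert trace["train_error"].iloc[-1] < trace["train_error"].iloc[0]


class TestSelectMLP:
    def test_single_cell_grid_equals_train(self):
        F = blobs(60, 4.0, seed=6)
        split = split_for(F)
        best, table = cl.select_mlp(F, split, FAST_RPROP, H_grid=(8,),
                                    restarts=1, seed=2)
        assert len(table) == 1
        assert best.H == 8

    def test_reproducible(self):
        F = blobs(60, 4.0, seed=7)
        split = split_for(F)
        a, ta = cl.select_mlp(F, split, FAST_RPROP, H_grid=(4, 8),
                              restarts=2, seed=2)
        b, tb = cl.select_mlp(F, split, FAST_RPROP, H_grid=(4, 8),
                              restarts=2, seed=2)
        np.testing.assert_array_equal(a.W1, b.W1)
        assert ta.equals(tb)


class TestSVM:
    def test_two_points_symmetric(self):
        F = FeatureMatrix(X=np.array([[1.0, 0.0], [-1.0, 0.0]]),
                          y=np.array([1, 0]),
                          pathology=np.array(["malignant", "normal"]),
                          site=np.array(["s", "s"]))
        split = cl.LearningSplit(train=np.array([0, 1]), val=np.array([], int),
                                 test=np.array([], int))
        model = cl.train_svm_rbf(F, split, 0.0, 5.0)
        d = model.decision_values(F.X)
        assert d[0] > 0 > d[1]
        assert d[0] == pytest.approx(-d[1], abs=1e-8)

    def test_stored_model_reproduces_trainer_decisions(self):
        from sklearn.svm import SVC
        F = blobs(80, 3.0, seed=8)
        split = split_for(F)
        model = cl.train_svm_rbf(F, split, -2.0, 3.0)
        ref = SVC(kernel="rbf", gamma=model.gamma, C=model.C)
        ysigned = np.where(F.y == 1, 1, -1)
        ref.fit(F.X[split.train], ysigned[split.train])
        np.testing.assert_allclose(model.decision_values(F.X),
                                   ref.decision_function(F.X), atol=1e-8)

    def test_margin_support_vector_scores_one(self):
        F = blobs(100, 4.0, seed=9)
        split = split_for(F)
        model = cl.train_svm_rbf(F, split, -2.0, 2.0)
        # free support vectors (|alpha| strictly inside the box) sit on the
        # +-1 margins
        free = np.abs(model.dual_coef) < model.C * (1 - 1e-8)
        if free.any():
            d = model.decision_values(model.support_vectors[free])
            # margin holds to the QP solver's KKT tolerance (1e-3)
            np.testing.assert_allclose(np.abs(d), 1.0, atol=5e-3)

    def test_xor_separated_with_rbf(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1, 1, 0, 0])
        F = FeatureMatrix(X=X, y=y,
                          pathology=np.where(y == 1, "malignant", "normal"),
                          site=np.array(["s"] * 4))
        split = cl.LearningSplit(train=np.arange(4), val=np.array([], int),
                                 test=np.array([], int))
        model = cl.train_svm_rbf(F, split, 1.0, 10.0)
        pred = cl.decide(model.decision_values(X), 0.0)
        np.testing.assert_array_equal(pred, y)

    def test_nonfinite_features_rejected(self):
        F = blobs(10, 1.0, seed=0)
        F.X[0, 0] = np.nan
        with pytest.raises(ValueError):
            cl.train_svm_rbf(F, split_for(F), 0.0, 0.0)


class TestGridSearch:
    def test_table_covers_grid(self):
        F = blobs(60, 3.0, seed=10)
        split = split_for(F)
        model, table = cl.grid_search_svm(F, split, COARSE_GAMMA_EXPS,
                                          COARSE_C_EXPS)
        assert len(table) == len(COARSE_GAMMA_EXPS) * len(COARSE_C_EXPS)
        assert table["val_success"].max() == pytest.approx(
            100 * np.mean(cl.decide(model.decision_values(F.X[split.val]), 0)
                          == F.y[split.val]))

    def test_single_cell_grid_equals_direct_training(self):
        F = blobs(60, 3.0, seed=11)
        split = split_for(F)
        m1, _ = cl.grid_search_svm(F, split, [-2.0], [3.0])
        m2 = cl.train_svm_rbf(F, split, -2.0, 3.0)
        np.testing.assert_array_equal(m1.support_vectors, m2.support_vectors)
        np.testing.assert_allclose(m1.dual_coef, m2.dual_coef)


class TestScoresAndDecide:
    def test_decide_thresholds_and_tie_rule(self):
        np.testing.assert_array_equal(
            cl.decide(np.array([0.4, 0.6]), 0.5), [0, 1])
        assert cl.decide(np.array([0.5]), 0.5)[0] == 0  # tie -> normal
        np.testing.assert_array_equal(
            cl.decide(np.array([-3.0, 0.1]), -np.inf), [1, 1])

    def test_scores_row_order_invariant(self):
        F = blobs(40, 3.0, seed=12)
        split = split_for(F)
        model = cl.train_svm_rbf(F, split, -1.0, 1.0)
        perm = np.random.default_rng(0).permutation(len(F.X))
        np.testing.assert_allclose(
            cl.predict_scores(model, F.X)[perm],
            cl.predict_scores(model, F.X[perm]), atol=1e-12)

    def test_mlp_scores_in_unit_interval(self):
        F = blobs(40, 3.0, seed=13)
        model, _ = cl.train_mlp(F, split_for(F), H=4, cfg=FAST_RPROP, seed=0)
        s = cl.predict_scores(model, F.X)
        assert np.all((s > 0) & (s < 1))
        assert cl.intermediate_threshold(model) == 0.5

    def test_dimension_mismatch(self):
        F = blobs(20, 3.0, seed=14)
        model = cl.train_svm_rbf(F, split_for(F), 0.0, 0.0)
        with pytest.raises(ValueError):
            cl.predict_scores(model, np.zeros((3, 5)))


class TestSplits:
    def test_partitions_disjoint_and_sized(self):
        y = np.r_[np.ones(80, int), np.zeros(120, int)]
        split = cl.LearningSplit.random(y, test_fraction=0.1,
                                        val_fraction=0.2, seed=0)
        assert len(split.test) == 20
        assert len(split.train) + len(split.val) == 180
        assert len(split.val) == 36  # 20% of the learning set
        all_idx = np.sort(np.r_[split.train, split.val, split.test])
        np.testing.assert_array_equal(all_idx, np.arange(200))

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            cl.LearningSplit(train=np.array([0, 1]), val=np.array([1]),
                             test=np.array([2]))
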
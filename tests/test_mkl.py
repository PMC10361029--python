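"""Kernel machinery: RBF, width heuristic, EasyMKL, SVM dual, prediction."""

import numpy as np
import pytest

from erpmkl.mkl import (KernelSet, combine_kernels, easymkl_fit, predict,
                        rbf_kernel, sigma_heuristic, svm_decision, svm_fit)
from erpmkl.validation import easymkl_grid_oracle, easymkl_toy_problems as _toy_problems


class TestRbfKernel:
    def test_unit_diagonal(self, rng):
        X = rng.standard_normal((6, 3))
        K = rbf_kernel(X, X, 0.7)
        assert np.allclose(np.diag(K), 1.0)

    def test_hand_computed_value(self):
        K = rbf_kernel([[0.0]], [[2.0]], 0.5)
        assert K[0, 0] == pytest.approx(np.exp(-2.0))

    def test_gram_symmetric_psd(self, rng):
        X = rng.standard_normal((10, 4))
        K = rbf_kernel(X, X, 1.3)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel([[np.nan]], [[0.0]], 1.0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel([[0.0]], [[0.0]], 0.0)


class TestSigmaHeuristic:
    def test_formula_substitution(self):
        # d = 2, pooled variance 0.25 -> sigma = 1 / (2 * 0.25) = 2
        X = np.array([[0.0, 0.5], [0.5, 1.0], [1.0, 0.0], [0.5, 0.5]])
        X = (X - X.mean()) / X.std() * 0.5  # force pooled variance 0.25
        assert sigma_heuristic(X) == pytest.approx(1.0 / (2 * 0.25))

    def test_zscored_block_gives_inverse_dimension(self, rng):
        X = rng.standard_normal((30, 8))
        X = (X - X.mean()) / X.std()
        assert sigma_heuristic(X) == pytest.approx(1.0 / 8, rel=1e-12)

    def test_constant_features_rejected(self):
        with pytest.raises(ValueError):
            sigma_heuristic(np.ones((5, 3)))




class TestEasyMKL:
    def test_identical_kernels_uniform_weights(self, rng):
        X = rng.standard_normal((8, 3))
        K = rbf_kernel(X, X, 0.5)
        y = np.array([1, 1, 1, 1, -1, -1, -1, -1])
        kset = KernelSet(source_ids=list(range(5)), matrices=[K.copy() for _ in range(5)])
        model = easymkl_fit(kset, y, lam=0.2)
        assert np.allclose(model.eta, 1 / np.sqrt(5), atol=1e-6)

    def test_separating_kernel_gets_top_weight(self, rng):
        n = 20
        y = np.array([+1] * 10 + [-1] * 10)
        sep = rbf_kernel(y[:, None] * 2.0, y[:, None] * 2.0, 0.25)
        mats = [sep]
        for _ in range(4):
            X = rng.standard_normal((n, 4))
            mats.append(rbf_kernel(X, X, 1 / 4))
        kset = KernelSet(source_ids=list(range(5)), matrices=mats)
        model = easymkl_fit(kset, y, lam=0.2)
        assert int(np.argmax(model.eta)) == 0

    @pytest.mark.parametrize("lam", [0.0, 0.2, 0.8])
    def test_matches_grid_search_oracle(self, lam):
        for kset, y in _toy_problems():
            model = easymkl_fit(kset, y, lam=lam)
            _, eta_ref = easymkl_grid_oracle(kset, y, lam, step=1e-3)
            assert np.abs(model.eta - eta_ref).max() <= 1e-2

    def test_weights_nonnegative_unit_norm(self, rng):
        for kset, y in _toy_problems():
            model = easymkl_fit(kset, y, lam=0.3)
            assert (model.eta >= 0).all()
            assert np.linalg.norm(model.eta) == pytest.approx(1.0)
            # per-class simplex distribution
            assert model.gamma_solution[y > 0].sum() == pytest.approx(1.0)
            assert model.gamma_solution[y < 0].sum() == pytest.approx(1.0)

    def test_l1_norm_option(self, rng):
        kset, y = _toy_problems()[3]
        model = easymkl_fit(kset, y, lam=0.2, weight_norm="L1")
        assert model.eta.sum() == pytest.approx(1.0)

    def test_single_class_rejected(self):
        kset, _ = _toy_problems()[0]
        with pytest.raises(ValueError):
            easymkl_fit(kset, np.array([1, 1]), lam=0.2)


class TestCombineKernels:
    def test_one_hot_returns_component(self, rng):
        kset, _ = _toy_problems()[3]
        out = combine_kernels(kset, np.array([1.0, 0.0]))
        assert np.array_equal(out, kset.matrices[0])

    def test_equal_weights_entrywise_mean(self):
        kset = KernelSet(source_ids=["a", "b"],
                         matrices=[np.eye(3), np.ones((3, 3))])
        out = combine_kernels(kset, np.array([0.5, 0.5]))
        assert np.allclose(out, (np.eye(3) + np.ones((3, 3))) / 2)

    def test_combination_stays_psd(self, rng):
        mats = []
        for _ in range(4):
            A = rng.standard_normal((8, 10))
            mats.append(A @ A.T)
        kset = KernelSet(source_ids=list(range(4)), matrices=mats)
        eta = rng.random(4)
        out = combine_kernels(kset, eta)
        assert np.linalg.eigvalsh(out).min() >= -1e-10

    def test_negative_weights_rejected(self):
        kset = KernelSet(source_ids=["a"], matrices=[np.eye(2)])
        with pytest.raises(ValueError):
            combine_kernels(kset, np.array([-0.1]))


class TestSvmDual:
    def test_two_point_closed_form(self):
        # k11 = k22 = 1, k12 = 0: dual solution alpha = (1, 1), b = 0
        K = np.eye(2)
        y = np.array([+1, -1])
        model = svm_fit(K, y, C=1.0)
        assert np.allclose(model.alpha, [1.0, 1.0], atol=1e-6)
        assert model.b == pytest.approx(0.0, abs=1e-6)
        pred = predict(model, [K])
        assert np.array_equal(pred, y)

    def test_constraints_hold_on_random_data(self, rng):
        X = np.vstack([rng.normal(1.5, 1, (10, 3)), rng.normal(-1.5, 1, (10, 3))])
        y = np.array([+1] * 10 + [-1] * 10)
        K = rbf_kernel(X, X, 0.3)
        model = svm_fit(K, y, C=1.0)
        assert (model.alpha >= -1e-12).all() and (model.alpha <= 1 + 1e-12).all()
        assert abs(model.alpha @ y) <= 1e-8

    def test_duplicating_points_keeps_decision(self, rng):
        X = np.vstack([rng.normal(1, 1, (6, 2)), rng.normal(-1, 1, (6, 2))])
        y = np.array([+1] * 6 + [-1] * 6)
        K = rbf_kernel(X, X, 0.5)
        model = svm_fit(K, y, C=1.0)
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, y])
        K2 = rbf_kernel(X2, X2, 0.5)
        model2 = svm_fit(K2, y2, C=0.5)  # halve C so total box mass matches
        Xt = rng.standard_normal((8, 2))
        d1 = svm_decision(model, rbf_kernel(Xt, X, 0.5))
        d2 = svm_decision(model2, rbf_kernel(Xt, X2, 0.5))
        assert np.allclose(d1, d2, atol=1e-5)

    def test_matches_reference_qp(self, rng):
        """Decision values agree with an independent high-precision solver."""
        from sklearn.svm import SVC
        for _ in range(5):
            X = rng.standard_normal((20, 4))
            y = np.where(rng.random(20) < 0.5, 1, -1)
            if abs(y.sum()) == 20:
                y[0] = -y[0]
            K = rbf_kernel(X, X, 0.4)
            model = svm_fit(K, y, C=1.0)
            ref = SVC(kernel="precomputed", C=1.0, tol=1e-10)
            ref.fit(K, y)
            ours = svm_decision(model, K)
            theirs = ref.decision_function(K)
            assert np.abs(ours - theirs).max() <= 1e-6

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            svm_fit(np.eye(3), np.array([1, 1, 1]))


class TestPredict:
    def test_one_hot_eta_reduces_to_single_kernel(self, rng):
        X = np.vstack([rng.normal(1, 1, (6, 2)), rng.normal(-1, 1, (6, 2))])
        y = np.array([+1] * 6 + [-1] * 6)
        K = rbf_kernel(X, X, 0.5)
        kset = KernelSet(source_ids=["a", "b"],
                         matrices=[K, rbf_kernel(rng.standard_normal((12, 2)),
                                                 rng.standard_normal((12, 2)), 0.5) * 0 + np.eye(12)])
        model = easymkl_fit(kset, y, lam=0.2)
        model.eta = np.array([1.0, 0.0])
        model = svm_fit(K, y, C=1.0, model=model)
        Xt = rng.standard_normal((5, 2))
        Kt = rbf_kernel(Xt, X, 0.5)
        multi = predict(model, [Kt, np.zeros((5, 12))])
        single = np.where(svm_decision(model, Kt) >= 0, 1, -1)
        assert np.array_equal(multi, single)

    def test_source_order_invariance_of_decision(self, rng):
        mats = [rng.random((4, 6)) for _ in range(3)]
        eta = np.array([0.2, 0.5, 0.3])
        model = svm_fit(np.eye(6), np.array([1, 1, 1, -1, -1, -1]), C=1.0)
        model.eta = eta
        d1 = predict(model, mats)
        perm = [2, 0, 1]
        model.eta = eta[perm]
        d2 = predict(model, [mats[p] for p in perm])
        assert np.array_equal(d1, d2)

    def test_source_mismatch_rejected(self):
        model = svm_fit(np.eye(2), np.array([1, -1]))
        model.eta = np.array([1.0])
        model.source_ids = ["a"]
        kset = KernelSet(source_ids=["b"], matrices=[np.eye(2)])
        with pytest.raises(ValueError):
            predict(model, kset)

    def test_zero_decision_maps_to_positive(self):
        model = svm_fit(np.eye(2), np.array([1, -1]))
        pred = predict(model, [np.zeros((1, 2))])
        assert pred[0] == +1


class TestKernelSetValidation:
    def test_validate_flags_asymmetry(self):
        K = np.eye(3)
        K[0, 1] = 0.5
        kset = KernelSet(source_ids=["a"], matrices=[K])
        with pytest.raises(ValueError, match="symmetric"):
            kset.validate()

    def test_validate_flags_indefinite(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        kset = KernelSet(source_ids=["a"], matrices=[K])
        with pytest.raises(ValueError, match="eigenvalue"):
            kset.validate()
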
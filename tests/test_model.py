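import dataclasses

import numpy as np
import pytest

from privsvm import (
    Hyperparams,
    KernelSpec,
    TrainingSet,
    augment_bias,
    build_dual_matrix,
    decision_scores,
    fit,
    kernel_matrix,
    predict,
    primal_diagnostics,
    privileged_block,
    qp_oracle,
)
from privsvm.model import FittedModel

from conftest import make_psd


class TestPrivilegedBlock:
    def test_all_ones_kernel_closed_form(self):
        # 11' has eigenvalues {2, 0}; 2/(1+1*2) = 2/3 on (1,1)/sqrt2 -> (1/3) 11'
        B = privileged_block(np.ones((2, 2)), gamma=1.0, C_tilde=1.0)
        np.testing.assert_allclose(B, np.ones((2, 2)) / 3, atol=1e-12)

    def test_c_tilde_zero_collapses_to_scaled_kernel(self, rng):
        K = make_psd(rng, 5)
        np.testing.assert_allclose(privileged_block(K, 2.0, 0.0), K / 2.0, atol=1e-12)

    def test_identity_kernel(self):
        B = privileged_block(np.eye(3), gamma=2.0, C_tilde=3.0)
        np.testing.assert_allclose(B, np.eye(3) / 5.0, atol=1e-12)

    def test_matches_direct_inverse(self, rng):
        K = make_psd(rng, 6, jitter=0.1)
        g, ct = 0.7, 1.3
        direct = K @ np.linalg.inv(g * np.eye(6) + ct * K)
        np.testing.assert_allclose(privileged_block(K, g, ct), direct, atol=1e-9)

    def test_result_symmetric_psd(self, rng):
        B = privileged_block(make_psd(rng, 8), gamma=0.5, C_tilde=2.0)
        assert np.abs(B - B.T).max() == 0.0
        assert np.linalg.eigvalsh(B).min() >= -1e-10

    def test_empty_block(self):
        assert privileged_block(np.zeros((0, 0)), 1.0, 1.0).shape == (0, 0)

    def test_invalid_gamma_raises(self):
        with pytest.raises(ValueError, match="gamma"):
            privileged_block(np.eye(2), 0.0, 1.0)


class TestBuildDualMatrix:
    def test_no_pi_block_structure(self):
        K = np.array([[2.0, 0.0], [0.0, 2.0]])
        G = build_dual_matrix(K, np.zeros((0, 0)), C=1.0, y=np.array([1, -1]), m=0)
        np.testing.assert_allclose(G, [[3.0, 0.0], [0.0, 3.0]], atol=1e-12)

    def test_full_pi_hand_assembly(self):
        B = np.ones((2, 2)) / 3
        K = 2 * np.eye(2)
        G = build_dual_matrix(K, B, C=1.0, y=np.array([1, 1]), m=2)
        np.testing.assert_allclose(
            G, [[2 + 1 / 3, 1 / 3], [1 / 3, 2 + 1 / 3]], atol=1e-12)

    def test_m_n_extremes(self, rng):
        K = make_psd(rng, 4)
        y = np.array([1, -1, 1, -1])
        G_full = build_dual_matrix(K, make_psd(rng, 4), C=2.0, y=y, m=4)
        G_none = build_dual_matrix(K, np.zeros((0, 0)), C=2.0, y=y, m=0)
        np.testing.assert_allclose(G_none, np.outer(y, y) * K + np.eye(4) / 2.0, atol=1e-12)
        assert G_full.shape == (4, 4)

    def test_symmetric_psd_for_valid_inputs(self, rng):
        for _ in range(5):
            n, m = 9, 4
            K = augment_bias(make_psd(rng, n))
            B = privileged_block(make_psd(rng, m), 1.0, 1.0)
            y = rng.choice([-1, 1], n)
            G = build_dual_matrix(K, B, C=3.0, y=y, m=m)
            assert np.abs(G - G.T).max() < 1e-10
            ev = np.linalg.eigvalsh(G)
            assert ev.min() >= -1e-8 * max(ev.max(), 1.0)

    def test_wrong_block_size_raises(self, rng):
        with pytest.raises(ValueError):
            build_dual_matrix(np.eye(4), np.eye(3), 1.0, np.array([1, -1, 1, -1]), m=2)


class TestFitToyModel:
    def test_alpha_and_scores(self, toy_two_point):
        data, hp = toy_two_point
        model = fit(data, hp)
        np.testing.assert_allclose(model.alpha, 0.5, atol=1e-8)
        # f(x) = 0.5(x+1) - 0.5(-x+1) = x
        np.testing.assert_allclose(
            decision_scores(model, [[0.7]]), [0.7], atol=1e-8)
        np.testing.assert_allclose(decision_scores(model, [[0.0]]), [0.0], atol=1e-10)

    def test_predict_signs_and_tie_rule(self, toy_two_point):
        data, hp = toy_two_point
        model = fit(data, hp)
        assert predict(model, [[0.7]]).tolist() == [1]
        assert predict(model, [[-0.3]]).tolist() == [-1]
        assert predict(model, [[0.0]]).tolist() == [1]  # zero score -> +1

    def test_separable_training_data_fully_separated(self, rng):
        # full PI, C_tilde=0, large gamma: behaves like hard margin
        X = np.vstack([rng.normal(3, 0.3, (15, 2)), rng.normal(-3, 0.3, (15, 2))])
        y = np.repeat([1, -1], 15)
        data = TrainingSet(X=X, X_priv=X.copy(), pi_mask=np.ones(30, dtype=bool), y=y)
        hp = Hyperparams(C=1.0, C_tilde=0.0, gamma=1e3,
                         kernel_main=KernelSpec("linear"), kernel_priv=KernelSpec("linear"))
        model = fit(data, hp)
        assert np.array_equal(predict(model, X), y)


class TestReductionsAndInvariances:
    def test_m0_equals_direct_no_pi_dual(self, rng, small_lupi_set):
        from privsvm import smo_solve

        data = small_lupi_set
        no_pi = TrainingSet(X=data.X, X_priv=None,
                            pi_mask=np.zeros(data.n, dtype=bool), y=data.y)
        hp = Hyperparams(C=2.0, kernel_main=KernelSpec("rbf", bandwidth=0.5),
                         kernel_priv=KernelSpec("rbf"))
        model = fit(no_pi, hp)
        # directly-constructed no-PI l2-SVM dual
        K = augment_bias(kernel_matrix(data.X, data.X, hp.kernel_main))
        G = np.outer(data.y, data.y) * K + np.eye(data.n) / hp.C
        alpha = smo_solve(0.5 * (G + G.T)).alpha
        Xq = rng.standard_normal((8, data.X.shape[1]))
        direct = (alpha * data.y) @ (kernel_matrix(data.X, Xq, hp.kernel_main) + 1.0)
        np.testing.assert_allclose(decision_scores(model, Xq), direct, atol=1e-8)

    def test_m0_invariant_to_priv_hyperparams(self, rng, small_lupi_set):
        data = small_lupi_set
        no_pi = TrainingSet(X=data.X, X_priv=None,
                            pi_mask=np.zeros(data.n, dtype=bool), y=data.y)
        Xq = rng.standard_normal((5, data.X.shape[1]))
        ref = None
        for ct, g in [(0.01, 0.1), (10.0, 5.0)]:
            hp = Hyperparams(C=1.0, C_tilde=ct, gamma=g)
            s = decision_scores(fit(no_pi, hp), Xq)
            if ref is None:
                ref = s
            else:
                np.testing.assert_allclose(s, ref, atol=1e-12)

    def test_sample_order_invariance(self, rng, small_lupi_set):
        data = small_lupi_set
        hp = Hyperparams(C=1.0, C_tilde=0.5, gamma=2.0)
        Xq = rng.standard_normal((10, data.X.shape[1]))
        base = decision_scores(fit(data, hp, tol=1e-9), Xq)
        perm = rng.permutation(data.n)
        shuffled = data.subset(perm)
        np.testing.assert_allclose(
            decision_scores(fit(shuffled, hp, tol=1e-9), Xq), base, atol=1e-6)

    def test_objective_matches_qp_oracle(self, small_lupi_set):
        data = small_lupi_set
        hp = Hyperparams(C=1.5, C_tilde=0.7, gamma=1.2)
        model = fit(data, hp, tol=1e-8)
        # rebuild G exactly as fit does and hand it to the generic QP oracle
        perm = model.permutation
        K = augment_bias(kernel_matrix(data.X[perm], data.X[perm], hp.kernel_main))
        Kt = augment_bias(kernel_matrix(data.X_priv[perm[:model.m]],
                                        data.X_priv[perm[:model.m]], hp.kernel_priv))
        G = build_dual_matrix(K, privileged_block(Kt, hp.gamma, hp.C_tilde),
                              hp.C, data.y[perm], model.m)
        obj_oracle = qp_oracle(G).objective
        assert abs(model.objective - obj_oracle) <= 1e-6 * (1 + abs(obj_oracle))


class TestPrecomputedKernel:
    def test_matches_linear_kernel_fit(self, rng, small_lupi_set):
        data = small_lupi_set
        hp_lin = Hyperparams(C=1.0, C_tilde=0.5, gamma=1.0,
                             kernel_main=KernelSpec("linear"))
        K = data.X @ data.X.T
        data_pre = TrainingSet(X=K, X_priv=data.X_priv, pi_mask=data.pi_mask, y=data.y)
        hp_pre = dataclasses.replace(hp_lin, kernel_main=KernelSpec("precomputed"))
        m_lin = fit(data, hp_lin, tol=1e-9)
        m_pre = fit(data_pre, hp_pre, tol=1e-9)
        Xq = rng.standard_normal((6, data.X.shape[1]))
        np.testing.assert_allclose(
            decision_scores(m_pre, Xq @ data.X.T),
            decision_scores(m_lin, Xq), atol=1e-6)


class TestPrimalDiagnostics:
    def test_m0_zeta_identity(self, toy_two_point):
        data, hp = toy_two_point
        model = fit(data, hp)
        diag = primal_diagnostics(model, data)
        assert diag.slack_fn_values.size == 0
        np.testing.assert_allclose(diag.zeta, model.alpha / hp.C, atol=1e-15)
        np.testing.assert_allclose(diag.zeta, [0.05, 0.05], atol=1e-8)

    def test_complementary_slackness_on_converged_fit(self, small_lupi_set):
        data = small_lupi_set
        model = fit(data, Hyperparams(C=2.0, C_tilde=1.0, gamma=1.0), tol=1e-8)
        assert model.converged
        diag = primal_diagnostics(model, data)
        active = model.alpha > 1e-6
        assert np.abs(diag.margin_residuals[active]).max() <= 1e-5
        assert diag.reliable


class TestSerialization:
    def test_round_trip_scores_identical(self, tmp_path, rng, small_lupi_set):
        data = small_lupi_set
        model = fit(data, Hyperparams(C=1.0, C_tilde=0.5, gamma=2.0))
        path = tmp_path / "model.json"
        model.save(path)
        loaded = FittedModel.load(path)
        Xq = rng.standard_normal((7, data.X.shape[1]))
        np.testing.assert_array_equal(
            decision_scores(loaded, Xq), decision_scores(model, Xq))

    def test_save_is_deterministic(self, tmp_path, small_lupi_set):
        model = fit(small_lupi_set, Hyperparams())
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        model.save(p1)
        model.save(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestTrainingSetValidation:
    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            TrainingSet(X=np.eye(2), X_priv=None,
                        pi_mask=np.zeros(2, dtype=bool), y=np.array([1, 1]))

    def test_non_pm1_labels_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            TrainingSet(X=np.eye(2), X_priv=None,
                        pi_mask=np.zeros(2, dtype=bool), y=np.array([0, 1]))

    def test_mask_without_priv_rejected(self):
        with pytest.raises(ValueError, match="X_priv"):
            TrainingSet(X=np.eye(2), X_priv=None,
                        pi_mask=np.array([True, False]), y=np.array([1, -1]))

    def test_nan_on_pi_row_rejected(self):
        Xp = np.array([[np.nan], [1.0]])
        with pytest.raises(ValueError, match="non-finite"):
            TrainingSet(X=np.eye(2), X_priv=Xp,
                        pi_mask=np.array([True, False]), y=np.array([1, -1]))

    def test_nan_on_non_pi_row_allowed(self):
        Xp = np.array([[np.nan], [1.0]])
        ts = TrainingSet(X=np.eye(2), X_priv=Xp,
                         pi_mask=np.array([False, True]), y=np.array([1, -1]))
        assert ts.m == 1
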
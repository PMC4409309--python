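"""The five learning machines against independent oracles and contracts."""

import numpy as np
import pytest
from scipy.optimize import minimize

from egmloc.learners import (
    HyperGrid,
    build_grid,
    fit_any,
    gaussian_kernel,
    krr_fit,
    krr_predict,
    mlp_fit,
    mlp_predict,
    multiclass_ovr,
    one_hot,
    ovr_predict,
    pnn_fit,
    pnn_predict,
    pnn_scores,
    predict_any,
    rbfnn_fit,
    rbfnn_predict,
    sigma_hat,
    svm_decision,
    svm_dual_objective,
    svm_fit,
    svm_predict,
)


def two_gaussians(n_per=20, sep=5.0, d=2, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(-sep / 2, 1, (n_per, d)), rng.normal(sep / 2, 1, (n_per, d))])
    y = np.array([0] * n_per + [1] * n_per)
    return X, y


class TestMLP:
    def test_xor_with_two_hidden_units(self):
        X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
        y = np.array([0, 1, 1, 0])
        best = 0.0
        for seed in range(10):
            model = mlp_fit(X, y, n_hidden=2, seed=seed)
            best = max(best, float(np.mean(mlp_predict(model, X) == y)))
            if best == 1.0:
                break
        assert best == 1.0

    def test_linearly_separable_single_unit(self):
        X, y = two_gaussians(n_per=20, sep=5.0)
        model = mlp_fit(X, y, n_hidden=1, seed=0)
        assert np.mean(mlp_predict(model, X) == y) == 1.0

    def test_output_layer_width_equals_class_count(self):
        X, y = two_gaussians()
        y = y.copy()
        y[:5] = 2  # three classes
        model = mlp_fit(X, y, n_hidden=3, seed=0)
        assert model.payload["W2"].shape[1] == 3

    def test_input_dimension_checked(self):
        X, y = two_gaussians()
        model = mlp_fit(X, y, n_hidden=2, seed=0)
        with pytest.raises(ValueError):
            mlp_predict(model, np.ones((3, 5)))


class TestRBFNN:
    def test_exact_interpolation_without_regularization(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 2))
        y = rng.integers(0, 3, 10)
        model = rbfnn_fit(X, y, width=1.0, regularization=0.0)
        from egmloc.learners import _rbfnn_outputs

        T = one_hot(y, model.classes)
        np.testing.assert_allclose(_rbfnn_outputs(model, X), T, atol=1e-6)
        assert np.array_equal(rbfnn_predict(model, X), y)

    def test_training_sse_nondecreasing_in_regularization(self):
        X, y = two_gaussians(n_per=15, sep=2.0, seed=2)
        from egmloc.learners import _rbfnn_outputs

        T = one_hot(y, np.unique(y))
        sses = []
        for reg in np.linspace(1e-3, 100.0, 10):
            model = rbfnn_fit(X, y, width=1.0, regularization=reg)
            sses.append(float(np.sum((_rbfnn_outputs(model, X) - T) ** 2)))
        assert all(a <= b + 1e-9 for a, b in zip(sses, sses[1:]))

    def test_weights_match_dense_linear_solve(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 3))
        y = rng.integers(0, 2, 12)
        reg = 0.5
        model = rbfnn_fit(X, y, width=1.2, regularization=reg)
        Phi = gaussian_kernel(X, X, 1.2)
        T = one_hot(y, model.classes)
        W_expect = np.linalg.inv(Phi.T @ Phi + reg * np.eye(12)) @ Phi.T @ T
        np.testing.assert_allclose(model.payload["W"], W_expect, atol=1e-8)

    def test_duplicate_inputs_at_zero_regularization(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 0, 1])
        model = rbfnn_fit(X, y, width=1.0, regularization=0.0)  # pinv path
        assert np.array_equal(rbfnn_predict(model, X), y)


class TestPNN:
    def test_two_point_symmetry(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([0, 1])
        model = pnn_fit(X, y, width=0.5)
        assert pnn_predict(model, np.array([[-0.2]]))[0] == 0
        assert pnn_predict(model, np.array([[0.2]]))[0] == 1

    def test_small_width_limit_is_nearest_neighbor(self):
        rng = np.random.default_rng(4)
        X, y = two_gaussians(n_per=25, sep=4.0, seed=4)
        model = pnn_fit(X, y, width=0.01)
        queries = rng.uniform(-4, 4, (100, 2))
        from scipy.spatial.distance import cdist

        nn = y[np.argmin(cdist(queries, X), axis=1)]
        assert np.array_equal(pnn_predict(model, queries), nn)

    def test_scores_match_brute_force_parzen_sums(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 3))
        y = rng.integers(0, 3, 20)
        w = 0.7
        model = pnn_fit(X, y, width=w)
        Q = rng.normal(size=(7, 3))
        scores = pnn_scores(model, Q)
        for qi, q in enumerate(Q):
            for ci, c in enumerate(model.classes):
                pts = X[y == c]
                brute = np.mean(
                    [np.exp(-np.sum((q - p) ** 2) / (2 * w**2)) for p in pts]
                )
                assert scores[qi, ci] == pytest.approx(brute, abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pnn_fit(np.ones((2, 1)), np.array([0, 0]), width=0.5)


class TestSVM:
    def test_two_point_max_margin_linear(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1, 1])
        model = svm_fit(X, y, C=1000.0, kernel="pk", degree=1)
        assert abs(svm_decision(model, np.array([[0.0]]))[0]) < 1e-3
        f = svm_decision(model, X)
        np.testing.assert_allclose(f, [-1.0, 1.0], atol=1e-3)
        assert model.payload["X_sv"].shape[0] == 2

    def test_kkt_margins_on_separable_data(self):
        X, y = two_gaussians(n_per=15, sep=6.0, seed=6)
        ypm = np.where(y == 0, -1, 1)
        model = svm_fit(X, ypm, C=10.0, kernel="gk", width=2.0)
        alpha = model.payload["alpha"]
        f = svm_decision(model, X)
        margin_svs = (alpha > 1e-8) & (alpha < 10.0 - 1e-8)
        assert margin_svs.any()
        assert np.abs(ypm[margin_svs] * f[margin_svs] - 1.0).max() < 1e-2

    @pytest.mark.parametrize("kernel,hyper", [("gk", {"width": 1.0}), ("pk", {"degree": 3})])
    def test_dual_objective_matches_qp_oracle(self, kernel, hyper):
        rng = np.random.default_rng(7)
        n = 16
        X = np.vstack([rng.normal(-1, 1, (n // 2, 2)), rng.normal(1, 1, (n // 2, 2))])
        y = np.array([-1.0] * (n // 2) + [1.0] * (n // 2))
        C = 5.0
        model = svm_fit(X, y, C=C, kernel=kernel, **hyper)
        from egmloc.learners import _svm_kernel

        K = _svm_kernel(kernel, X, X, {"width": hyper.get("width"), "degree": hyper.get("degree")})
        Q = np.outer(y, y) * K

        def neg_dual(a):
            return -(a.sum() - 0.5 * a @ Q @ a)

        res = minimize(
            neg_dual,
            np.zeros(n),
            jac=lambda a: -(np.ones(n) - Q @ a),
            bounds=[(0, C)] * n,
            constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
            method="SLSQP",
            options={"maxiter": 1000, "ftol": 1e-12},
        )
        assert svm_dual_objective(model, X) == pytest.approx(-res.fun, abs=1e-3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            svm_fit(np.ones((3, 1)), np.array([1, 1, 1]), C=1.0, kernel="gk", width=1.0)


class TestOVR:
    def test_two_class_degenerate_case_matches_binary(self):
        X, y = two_gaussians(n_per=20, sep=3.0, seed=8)
        binary = svm_fit(X, np.where(y == 0, -1, 1), C=10.0, kernel="gk", width=1.0)
        ovr = multiclass_ovr(
            lambda Xt, ypm: svm_fit(Xt, ypm, C=10.0, kernel="gk", width=1.0), X, y
        )
        rng = np.random.default_rng(9)
        Q = rng.uniform(-3, 3, (50, 2))
        bin_pred = np.where(svm_decision(binary, Q) < 0, 0, 1)
        assert np.array_equal(ovr_predict(ovr, Q), bin_pred)

    def test_eight_separated_clusters_fit_exactly(self):
        rng = np.random.default_rng(10)
        centers = np.array(
            [[i, j, k] for i in (-4, 4) for j in (-4, 4) for k in (-4, 4)], dtype=float
        )
        X = np.vstack([c + rng.normal(0, 0.3, (10, 3)) for c in centers])
        y = np.repeat(np.arange(8), 10)
        model = multiclass_ovr(
            lambda Xt, ypm: svm_fit(Xt, ypm, C=100.0, kernel="gk", width=2.0), X, y
        )
        assert np.mean(ovr_predict(model, X) == y) == 1.0
        assert len(model.payload["machines"]) == 8


class TestKRR:
    def test_interpolation_limit(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(15, 2))
        Y = rng.normal(size=(15, 3))
        # a width near the point spacing keeps the kernel well conditioned
        model = krr_fit(X, Y, regularization=1e-10, width=0.8)
        np.testing.assert_allclose(krr_predict(model, X), Y, atol=1e-4)

    def test_linear_kernel_matches_closed_form_ridge(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 3))
        Y = rng.normal(size=(30, 3))
        lam = 0.7
        model = krr_fit(X, Y, regularization=lam, kernel="linear")
        # dual ridge == primal ridge without intercept
        W = np.linalg.solve(X.T @ X + lam * np.eye(3), X.T @ Y)
        np.testing.assert_allclose(krr_predict(model, X), X @ W, atol=1e-8)

    def test_coefficients_match_dense_solve(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(20, 4))
        Y = rng.normal(size=(20, 3))
        lam, w = 0.3, 1.1
        model = krr_fit(X, Y, regularization=lam, width=w)
        K = gaussian_kernel(X, X, w)
        A = np.linalg.solve(K + lam * np.eye(20), Y)
        np.testing.assert_allclose(model.payload["A"], A, atol=1e-8)

    def test_singular_system_raises(self):
        X = np.zeros((4, 2))  # duplicate inputs
        Y = np.arange(8.0).reshape(4, 2)
        with pytest.raises(np.linalg.LinAlgError):
            krr_fit(X, Y, regularization=0.0, width=1.0)


class TestSigmaHat:
    def test_two_points(self):
        assert sigma_hat(np.array([[0.0, 0], [3.0, 0]])) == pytest.approx(3.0)

    def test_identical_points(self):
        assert sigma_hat(np.zeros((5, 3))) == 0.0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(15, 3))
        acc, cnt = 0.0, 0
        for i in range(15):
            for j in range(i + 1, 15):
                acc += np.linalg.norm(X[i] - X[j])
                cnt += 1
        assert sigma_hat(X) == pytest.approx(acc / cnt, abs=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            sigma_hat(np.ones((1, 3)))


class TestGrids:
    def test_mlp_grid(self):
        assert build_grid("mlp").params["n_hidden"] == list(range(1, 11))

    def test_rbfnn_grid_linear_spacing(self):
        g = build_grid("rbfnn")
        for name in ("regularization", "width"):
            vals = np.array(g.params[name])
            assert vals.size == 10
            assert vals[0] == pytest.approx(1e-3) and vals[-1] == pytest.approx(1e2)
            np.testing.assert_allclose(np.diff(vals), np.diff(vals)[0])

    def test_pnn_grid(self):
        vals = np.array(build_grid("pnn").params["width"])
        assert vals.size == 10 and vals[0] == 0.1 and vals[-1] == 1.0

    def test_svm_grids_log_spacing(self):
        g = build_grid("svm-gk")
        C = np.array(g.params["C"])
        w = np.array(g.params["width"])
        assert C.size == 10 and C[0] == pytest.approx(10.0) and C[-1] == pytest.approx(1e3)
        assert w.size == 20 and w[0] == pytest.approx(1e-2) and w[-1] == pytest.approx(10.0)
        np.testing.assert_allclose(w[1:] / w[:-1], (w[1] / w[0]))
        pk = build_grid("svm-pk")
        assert pk.params["degree"] == list(range(1, 11))

    def test_krr_grid_scaled_by_sigma(self):
        g = build_grid("krr", sigma=2.0)
        reg = np.array(g.params["regularization"])
        w = np.array(g.params["width"])
        assert reg.size == 50 and reg[0] == pytest.approx(1e-3) and reg[-1] == pytest.approx(10.0)
        assert w.size == 50 and w[0] == pytest.approx(0.2) and w[-1] == pytest.approx(200.0)

    def test_grid_points_order_and_membership(self):
        g = HyperGrid("svm-gk", {"C": [1.0, 2.0], "width": [0.5, 1.0]})
        pts = g.points()
        assert pts == [
            {"C": 1.0, "width": 0.5},
            {"C": 1.0, "width": 1.0},
            {"C": 2.0, "width": 0.5},
            {"C": 2.0, "width": 1.0},
        ]

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            build_grid("forest")


class TestDeterminismAndInvariance:
    @pytest.mark.parametrize("kind,hyper", [
        ("rbfnn", {"width": 1.0, "regularization": 0.1}),
        ("pnn", {"width": 0.5}),
        ("svm-gk", {"C": 10.0, "width": 1.0}),
    ])
    def test_row_permutation_invariance(self, kind, hyper):
        X, y = two_gaussians(n_per=15, sep=3.0, seed=15)
        rng = np.random.default_rng(16)
        perm = rng.permutation(len(y))
        Q = rng.uniform(-3, 3, (40, 2))
        a = predict_any(fit_any(kind, X, y, hyper, seed=0), Q)
        b = predict_any(fit_any(kind, X[perm], y[perm], hyper, seed=0), Q)
        assert np.array_equal(a, b)

    def test_krr_permutation_invariance(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(25, 3))
        Y = rng.normal(size=(25, 3))
        perm = rng.permutation(25)
        Q = rng.normal(size=(10, 3))
        a = krr_predict(krr_fit(X, Y, 0.1, 1.0), Q)
        b = krr_predict(krr_fit(X[perm], Y[perm], 0.1, 1.0), Q)
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_seeded_mlp_is_deterministic(self):
        X, y = two_gaussians(seed=18)
        m1 = mlp_fit(X, y, n_hidden=3, seed=5)
        m2 = mlp_fit(X, y, n_hidden=3, seed=5)
        assert np.array_equal(m1.payload["W1"], m2.payload["W1"])
        assert np.array_equal(m1.payload["W2"], m2.payload["W2"])
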
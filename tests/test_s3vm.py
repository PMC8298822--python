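"""Semi-supervised SVM: subproblem solvers, block descent, and prediction."""

import numpy as np
import pytest
import scipy.optimize

from s3seg.data import FeatureMatrix, Laplacian, PartialLabels
from s3seg.errors import DataError, NumericalError
from s3seg.graph import laplacian
from s3seg.s3vm import (
    S3VMModel,
    S3VMParams,
    evaluate_objective,
    fit,
    predict,
    project_simplex,
    svm_dual_fit,
    update_embedding,
    update_similarity,
    update_svm,
)
from s3seg.synthetic import generate_clusters

from conftest import separable_2d


def primal_svm_oracle(X, y):
    """Independent hard-margin oracle: solve the primal QP directly."""
    d = X.shape[1]

    def obj(z):
        return 0.5 * z[:d] @ z[:d]

    def jac(z):
        g = np.zeros(d + 1)
        g[:d] = z[:d]
        return g

    cons = [{"type": "ineq",
             "fun": lambda z, i=i: y[i] * (X[i] @ z[:d] + z[d]) - 1.0}
            for i in range(X.shape[0])]
    res = scipy.optimize.minimize(obj, np.zeros(d + 1), jac=jac, method="SLSQP",
                                  constraints=cons,
                                  options={"maxiter": 500, "ftol": 1e-12})
    return res.x[:d], res.x[d]


class TestSvmDualFit:
    def test_two_point_kkt_by_hand(self):
        fm = FeatureMatrix(np.array([[1.0, 0.0], [-1.0, 0.0]]), ["a", "b"])
        sol = svm_dual_fit(fm, [1, -1])
        np.testing.assert_allclose(sol.w, [1.0, 0.0], atol=1e-8)
        assert sol.b == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(sol.alpha, [0.5, 0.5], atol=1e-8)

    def test_four_point_symmetric_support(self):
        fm = FeatureMatrix(
            np.array([[1.0, 1.0], [2.0, 2.0], [-1.0, -1.0], [-2.0, -2.0]]),
            list("abcd"))
        sol = svm_dual_fit(fm, [1, 1, -1, -1])
        np.testing.assert_allclose(sol.w, [0.5, 0.5], atol=1e-7)
        assert sol.b == pytest.approx(0.0, abs=1e-7)
        assert sorted(sol.support_indices.tolist()) == [0, 2]

    @pytest.mark.parametrize("seed", range(5))
    def test_margin_width_and_dual_feasibility(self, seed):
        fm, y = separable_2d(10, gap=5.0, seed=seed)
        sol = svm_dual_fit(fm, y)
        X = fm.values
        margins = y * (X @ sol.w + sol.b)
        assert margins.min() >= 1.0 - 1e-6  # all points classified correctly
        # support vectors sit exactly on the margin boundary
        np.testing.assert_allclose(margins[sol.support_indices], 1.0, atol=1e-6)
        assert sol.alpha @ y == pytest.approx(0.0, abs=1e-8)
        assert np.all(sol.alpha >= 0)
        np.testing.assert_allclose((sol.alpha * y) @ X, sol.w, atol=1e-8)
        # margin width is 2/||w||, matched against the primal oracle
        w0, _ = primal_svm_oracle(X, y)
        assert 2 / np.linalg.norm(sol.w) == pytest.approx(
            2 / np.linalg.norm(w0), rel=1e-4)

    def test_single_class_rejected(self):
        fm, _ = separable_2d(5, gap=4.0, seed=0)
        with pytest.raises(DataError):
            svm_dual_fit(fm, np.ones(10))

    def test_non_separable_rejected(self):
        # XOR layout has no separating hyperplane
        X = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        fm = FeatureMatrix(X, list("abcd"))
        with pytest.raises(NumericalError, match="update_svm"):
            svm_dual_fit(fm, [1, 1, -1, -1])


class TestEvaluateObjective:
    def _zero_model(self, n, d, c=2):
        F = np.zeros((n, c))
        F[:c, :c] = np.eye(c)
        return S3VMModel(w=np.zeros(d), b=0.0, s=np.zeros((n, n)), F=F,
                         y_full=np.ones(n, dtype=int))

    def test_zero_model_reduces_to_hinge_sum(self):
        n, d = 6, 3
        params = S3VMParams(lambda1=2.0, gamma_unlabeled=0.25)
        X = FeatureMatrix(np.arange(n * d, dtype=float).reshape(n, d),
                          [str(i) for i in range(n)])
        labels = PartialLabels(np.array([1, -1, 1, 0, 0, 0]))
        val = evaluate_objective(self._zero_model(n, d), X, labels, params)
        # every margin term is exactly 1, weighted 1 or gamma
        assert val == pytest.approx(2.0 * (3 * 1.0 + 3 * 0.25), abs=1e-12)

    def test_matches_term_by_term_oracle(self, rng):
        n, d, c = 8, 3, 2
        X = rng.normal(size=(n, d))
        w = rng.normal(size=d)
        b = 0.3
        s = rng.uniform(size=(n, n))
        np.fill_diagonal(s, 0)
        s /= s.sum(1, keepdims=True)
        F = np.linalg.qr(rng.normal(size=(n, c)))[0]
        y = rng.choice([1, -1], size=n)
        labels = PartialLabels(np.where(np.arange(n) < 4, y, 0))
        params = S3VMParams(lambda1=1.5, lambda2=0.2, lambda3=0.7, lambda4=0.9,
                            gamma_unlabeled=0.1)
        model = S3VMModel(w=w, b=b, s=s, F=F, y_full=y)
        got = evaluate_objective(model, FeatureMatrix(X, [str(i) for i in range(n)]),
                                 labels, params)
        # literal term-by-term recomputation
        sym = 0.5 * (s + s.T)
        L = np.diag(sym.sum(1)) - sym
        u = np.where(labels.labels != 0, 1.0, 0.1)
        expected = 0.5 * w @ w
        expected += 1.5 * sum(u[i] * max(0.0, 1 - (w @ X[i] + b) * y[i])
                              for i in range(n))
        expected += 0.2 * (X @ w) @ L @ (X @ w)
        expected += 0.7 * (s**2).sum()
        expected += 0.9 * np.trace(F.T @ L @ F)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got >= 0.0


class TestUpdateEmbedding:
    def test_zero_laplacian(self):
        F = update_embedding(np.zeros((6, 6)), 2)
        np.testing.assert_allclose(F.T @ F, np.eye(2), atol=1e-10)
        assert np.trace(F.T @ np.zeros((6, 6)) @ F) == 0.0

    def test_disconnected_components_null_space(self):
        # two components -> two zero eigenvalues; embedding constant per block
        s = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (3, 4), (4, 5)]:
            s[i, j] = s[j, i] = 0.5
        lap = laplacian(s)
        F = update_embedding(lap, 2)
        assert np.trace(F.T @ lap.L @ F) == pytest.approx(0.0, abs=1e-10)
        for col in F.T:
            for block in (col[:3], col[3:]):
                nz = block[np.abs(block) > 1e-9]
                if nz.size:
                    np.testing.assert_allclose(block, block[0], atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_trace_equals_smallest_eigenvalues(self, seed):
        r = np.random.default_rng(seed)
        A = r.normal(size=(12, 12))
        L = A @ A.T  # random PSD
        F = update_embedding(L, 3)
        evals = np.linalg.eigvalsh(L)
        assert np.trace(F.T @ L @ F) == pytest.approx(evals[:3].sum(), abs=1e-8)
        np.testing.assert_allclose(F.T @ F, np.eye(3), atol=1e-10)

    def test_c_embed_too_large(self):
        with pytest.raises(DataError):
            update_embedding(np.zeros((4, 4)), 4)


def simplex_qp_oracle(e, lam3):
    """Generic simplex-constrained QP: min e.s + 2 lam3 ||s||^2."""
    m = e.size
    res = scipy.optimize.minimize(
        lambda s: e @ s + 2 * lam3 * s @ s,
        np.full(m, 1.0 / m),
        jac=lambda s: e + 4 * lam3 * s,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * m,
        constraints=[{"type": "eq", "fun": lambda s: s.sum() - 1.0,
                      "jac": lambda s: np.ones(m)}],
        options={"maxiter": 300, "ftol": 1e-14},
    )
    return res.x


class TestUpdateSimilarity:
    def test_symmetric_costs_give_uniform_row(self):
        assert np.allclose(project_simplex(np.array([0.0, 0.0])), [0.5, 0.5])

    def test_hand_solved_vertex_solution(self):
        # min 8 s2 + 2(s1^2 + s2^2) on the simplex -> (1, 0)
        np.testing.assert_allclose(
            project_simplex(np.array([0.0, -8.0]) / 4.0), [[1.0, 0.0]])

    @pytest.mark.parametrize("seed", range(25))
    def test_rows_match_qp_oracle(self, seed):
        r = np.random.default_rng(seed)
        m = int(r.integers(2, 11))
        e = r.uniform(0, 5, size=m)
        lam3 = float(r.uniform(0.2, 3.0))
        ours = project_simplex(-e / (4 * lam3))[0]
        oracle = simplex_qp_oracle(e, lam3)
        np.testing.assert_allclose(ours, oracle, atol=1e-6)

    def test_full_update_feasible_and_diagonal_zero(self, rng):
        n, d = 12, 3
        X = FeatureMatrix(rng.normal(size=(n, d)), [str(i) for i in range(n)])
        F = np.linalg.qr(rng.normal(size=(n, 2)))[0]
        params = S3VMParams(lambda2=0.3, lambda3=1.1, lambda4=0.8)
        s = update_similarity(X, rng.normal(size=d), F, params)
        np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(s >= 0) and np.all(np.diag(s) == 0)

    def test_lambda3_required_positive(self, rng):
        X = FeatureMatrix(rng.normal(size=(5, 2)), list("abcde"))
        with pytest.raises(DataError):
            update_similarity(X, np.zeros(2), np.zeros((5, 2)),
                              S3VMParams(lambda3=0.0))


class TestUpdateSvm:
    def test_hard_margin_limit_matches_dual(self):
        fm, y = separable_2d(15, gap=5.0, seed=3)
        hard = svm_dual_fit(fm, y)
        n = fm.n
        L0 = Laplacian(np.zeros((n, n)), np.zeros((n, n)))
        w, b = update_svm(fm, y, np.ones(n), L0,
                          S3VMParams(lambda1=1e5, lambda2=0.0))
        cos = w @ hard.w / (np.linalg.norm(w) * np.linalg.norm(hard.w))
        assert np.arccos(np.clip(cos, -1, 1)) < 1e-3

    def test_duplicating_samples_equals_halving_lambda1(self):
        fm, y = separable_2d(8, gap=3.0, seed=7)
        n = fm.n
        L0 = Laplacian(np.zeros((n, n)), np.zeros((n, n)))
        w1, b1 = update_svm(fm, y, np.ones(n), L0,
                            S3VMParams(lambda1=0.5, lambda2=0.0))
        X2 = np.vstack([fm.values, fm.values])
        fm2 = FeatureMatrix(X2, [f"r{i}" for i in range(2 * n)])
        L02 = Laplacian(np.zeros((2 * n, 2 * n)), np.zeros((2 * n, 2 * n)))
        w2, b2 = update_svm(fm2, np.concatenate([y, y]), np.ones(2 * n), L02,
                            S3VMParams(lambda1=0.25, lambda2=0.0))
        np.testing.assert_allclose(w1, w2, atol=1e-5)
        assert b1 == pytest.approx(b2, abs=1e-5)

    def test_non_finite_rejected(self):
        X = np.array([[np.inf, 0.0], [0.0, 1.0]])
        fm = None
        with pytest.raises(DataError):
            update_svm(X, np.array([1.0, -1.0]), np.ones(2),
                       Laplacian(np.zeros((2, 2)), np.zeros((2, 2))),
                       S3VMParams())


class TestFit:
    def test_fully_labeled_reduces_to_svm(self):
        fm, y = separable_2d(12, gap=4.0, seed=2)
        labels = PartialLabels(y.astype(int))
        params = S3VMParams(k=5, max_iter=5)
        model = fit(fm, labels, params)
        np.testing.assert_array_equal(model.y_full, y.astype(int))
        np.testing.assert_array_equal(predict(model, fm), y.astype(int))

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_trace_non_increasing(self, seed):
        ds = generate_clusters(60, 2, 4.0, 0.1, seed)
        model = fit(ds.X, ds.labels_partial, S3VMParams(k=6, max_iter=8))
        trace = np.asarray(model.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9)
        # labeled entries never change
        lab = ds.labels_partial.labeled_mask
        np.testing.assert_array_equal(model.y_full[lab],
                                      ds.labels_partial.labels[lab])
        # embedding stays orthonormal
        np.testing.assert_allclose(model.F.T @ model.F,
                                   np.eye(model.F.shape[1]), atol=1e-8)

    def test_single_class_labels_rejected(self):
        ds = generate_clusters(30, 2, 4.0, 0.2, 0)
        bad = np.abs(ds.labels_partial.labels)  # all revealed labels +1
        with pytest.raises(DataError):
            fit(ds.X, PartialLabels(bad), S3VMParams(k=5))

    def test_too_few_samples_for_k(self):
        ds = generate_clusters(8, 2, 4.0, 1.0, 0)
        with pytest.raises(DataError, match="k"):
            fit(ds.X, ds.labels_partial, S3VMParams(k=10))


class TestPredict:
    def test_tie_maps_to_positive(self):
        model = S3VMModel(w=np.array([1.0, 0.0]), b=0.0, s=np.zeros((2, 2)),
                          F=np.eye(2), y_full=np.array([1, -1]))
        assert predict(model, np.array([[0.0, 3.0]]))[0] == 1

    def test_decision_values_match_dot_product(self, rng):
        w = rng.normal(size=3)
        model = S3VMModel(w=w, b=0.25, s=np.zeros((2, 2)), F=np.eye(2),
                          y_full=np.array([1, -1]))
        Xn = rng.normal(size=(20, 3))
        expected = np.where(Xn @ w + 0.25 >= 0, 1, -1)
        np.testing.assert_array_equal(predict(model, Xn), expected)

    def test_dimension_mismatch(self):
        model = S3VMModel(w=np.zeros(3), b=0.0, s=np.zeros((2, 2)),
                          F=np.eye(2), y_full=np.array([1, -1]))
        with pytest.raises(DataError):
            predict(model, np.zeros((4, 2)))
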
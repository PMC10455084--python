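"""Weighted SVDD: solver correctness, geometry, KKT conditions."""

import numpy as np
import pytest
from scipy.optimize import minimize

from leafosr.core import FeatureTable, KernelSpec, SampleWeights, gram_matrix
from leafosr.wsvdd import (
    default_weights,
    fit,
    fit_oneclass,
    model_from_json,
    model_to_json,
    predict_membership,
    solve_dual,
    squared_center_distance,
)


def qp_oracle_objective(K, upper):
    """Dense general-purpose QP solve (SLSQP) of the wSVDD dual."""
    n = K.shape[0]
    diag = np.diag(K)

    def neg_obj(a):
        return -(diag @ a - a @ K @ a)

    def neg_grad(a):
        return -(diag - 2.0 * K @ a)

    starts = [np.minimum(np.full(n, 1.0 / n), upper)]
    starts[0] = np.clip(
        starts[0] + (1.0 - starts[0].sum()) * upper / upper.sum(), 0, upper
    )
    gen = np.random.default_rng(0)
    for _ in range(4):  # extra feasible starts in case SLSQP stalls
        x = gen.dirichlet(np.ones(n))
        starts.append(np.clip(x, 0, upper))
    best = None
    for x0 in starts:
        res = minimize(
            neg_obj,
            x0,
            jac=neg_grad,
            bounds=[(0.0, u) for u in upper],
            constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0}],
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        feasible = (
            abs(res.x.sum() - 1.0) < 1e-8
            and np.all(res.x >= -1e-9)
            and np.all(res.x <= upper + 1e-9)
        )
        if res.success and feasible and (best is None or -res.fun > best):
            best = -res.fun
    assert best is not None, "QP oracle failed from every start"
    return best


def dual_objective(K, a):
    return float(np.diag(K) @ a - a @ K @ a)


def random_instance(rng, kind):
    n = int(rng.integers(2, 21))
    d = int(rng.integers(1, 6))
    X = rng.standard_normal((n, d))
    spec = KernelSpec(kind, gamma=float(rng.uniform(0.1, 2.0)))
    scheme = rng.choice(["uniform", "centroid"])
    w = default_weights(X, spec, scheme=scheme)
    # ensure feasibility with headroom: sum(C*w) in [1.2, 4]
    C = float(rng.uniform(1.2, 4.0)) / w.w.sum()
    return X, spec, w, C


class TestDefaultWeights:
    def test_uniform_all_ones(self, rng, rbf_half):
        w = default_weights(rng.standard_normal((6, 2)), rbf_half, "uniform")
        assert np.array_equal(w.w, np.ones(6))

    def test_outlier_gets_smaller_weight(self, linear):
        X = np.array([[0.0], [0.0], [10.0]])
        w = default_weights(X, linear, "centroid").w
        assert w[2] < w[0] == w[1] == 1.0

    def test_single_point(self, rbf_half):
        assert np.array_equal(default_weights(np.zeros((1, 3)), rbf_half, "centroid").w, [1.0])

    def test_identical_points_all_one(self, rbf_half):
        X = np.ones((5, 2))
        assert np.array_equal(default_weights(X, rbf_half, "centroid").w, np.ones(5))

    def test_weights_decrease_with_centroid_distance(self, rng, rbf_half):
        X = rng.standard_normal((12, 3))
        K = gram_matrix(X, rbf_half)
        d2 = np.diag(K) - 2 * K.mean(axis=1) + K.mean()
        w = default_weights(X, rbf_half, "centroid").w
        order = np.argsort(d2)
        assert np.all(np.diff(w[order]) <= 1e-12)

    def test_empty_errors(self, rbf_half):
        with pytest.raises(ValueError):
            default_weights(np.zeros((0, 2)), rbf_half, "centroid")


class TestSolveDual:
    def test_single_sample_forced(self, rbf_half):
        a = solve_dual(np.array([[1.0]]), SampleWeights([1.0]), C=5.0)
        assert np.array_equal(a, [1.0])

    def test_minimal_enclosing_ball_alphas(self, meb_table, linear):
        K = gram_matrix(meb_table.X, linear)
        a = solve_dual(K, SampleWeights(np.ones(3)), C=10.0)
        assert a == pytest.approx([0.5, 0.5, 0.0], abs=1e-5)
        center = a @ meb_table.X
        assert center == pytest.approx([1.0, 0.0], abs=1e-5)

    def test_alphas_sum_to_one_and_in_box(self, rng):
        for _ in range(5):
            X, spec, w, C = random_instance(rng, "rbf")
            a = solve_dual(gram_matrix(X, spec), w, C)
            assert a.sum() == pytest.approx(1.0, abs=1e-8)
            assert np.all(a >= -1e-12) and np.all(a <= C * w.w + 1e-6)

    def test_infeasible_advises_larger_C(self):
        K = np.eye(3)
        with pytest.raises(ValueError, match="[Cc]"):
            solve_dual(K, SampleWeights(np.ones(3)), C=0.1)

    def test_rejects_non_psd(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="semidefinite"):
            solve_dual(K, SampleWeights(np.ones(2)), C=5.0)

    def test_rejects_asymmetric(self):
        K = np.array([[1.0, 0.5], [0.1, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            solve_dual(K, SampleWeights(np.ones(2)), C=5.0)

    @pytest.mark.parametrize("kind", ["rbf", "linear"])
    def test_objective_matches_qp_oracle(self, kind):
        rng = np.random.default_rng(99)
        for _ in range(8):
            X, spec, w, C = random_instance(rng, kind)
            K = gram_matrix(X, spec)
            a = solve_dual(K, w, C)
            oracle = qp_oracle_objective(K, C * w.w)
            assert dual_objective(K, a) == pytest.approx(oracle, abs=1e-6)


class TestFit:
    def test_single_point_model(self, rbf_half):
        t = FeatureTable(ids=["a"], labels=["x"], X=np.array([[1.0, 2.0]]))
        m = fit(t, SampleWeights([1.0]), C=5.0, kernel=rbf_half)
        assert m.r2 == pytest.approx(0.0, abs=1e-9)
        assert squared_center_distance(m, [1.0, 2.0]) == pytest.approx(0.0, abs=1e-9)

    def test_meb_radius_and_distances(self, meb_table, linear):
        m = fit(meb_table, SampleWeights(np.ones(3)), C=10.0, kernel=linear)
        assert m.r2 == pytest.approx(1.0, abs=1e-5)
        assert squared_center_distance(m, [1.0, 1.0]) == pytest.approx(1.0, abs=1e-5)
        assert squared_center_distance(m, [3.0, 0.0]) == pytest.approx(4.0, abs=1e-5)

    def test_uniform_weights_reproduce_standard_svdd(self, rng, rbf_half):
        X = rng.standard_normal((15, 3))
        t = FeatureTable(
            ids=[str(i) for i in range(15)], labels=["x"] * 15, X=X
        )
        m1 = fit(t, SampleWeights(np.ones(15)), C=0.3, kernel=rbf_half)
        m2 = fit_oneclass(t, C=0.3, kernel=rbf_half, variant="svdd")
        assert np.array_equal(m1.alphas, m2.alphas)
        assert m1.r2 == m2.r2

    def test_kkt_conditions_hold(self, rng):
        for _ in range(5):
            X, spec, w, C = random_instance(rng, "rbf")
            n = X.shape[0]
            t = FeatureTable([str(i) for i in range(n)], ["x"] * n, X)
            m = fit(t, w, C, spec)
            K = gram_matrix(X, spec)
            a = solve_dual(K, w, C)
            d2 = np.diag(K) - 2 * K @ a + a @ K @ a
            upper = C * w.w
            tol = 1e-4
            # non-bound-capped points lie inside or on the sphere
            inside = a < upper - m.tol
            assert np.all(d2[inside] <= m.r2 + tol)
            # points with positive slack sit at their upper bound
            slack = d2 > m.r2 + tol
            assert np.all(np.abs(a[slack] - upper[slack]) <= m.tol * 10)

    def test_support_vector_count_monotone_in_C(self, rng, rbf_half):
        X = rng.standard_normal((20, 2))
        t = FeatureTable([str(i) for i in range(20)], ["x"] * 20, X)
        counts = []
        for C in [1.0, 0.5, 0.25, 0.12, 0.08]:
            m = fit(t, SampleWeights(np.ones(20)), C, rbf_half)
            counts.append(m.n_support)
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestPredictMembership:
    def test_boundary_sv_accepted_with_zero_score(self, meb_table, linear):
        m = fit(meb_table, SampleWeights(np.ones(3)), C=10.0, kernel=linear)
        acc, score = predict_membership(m, meb_table)
        assert acc[0] and acc[1]
        assert score[0] == pytest.approx(0.0, abs=1e-5)

    def test_outside_point_rejected(self, meb_table, linear):
        m = fit(meb_table, SampleWeights(np.ones(3)), C=10.0, kernel=linear)
        acc, score = predict_membership(
            m, FeatureTable(["z"], ["?"], np.array([[3.0, 0.0]]))
        )
        assert not acc[0] and score[0] == pytest.approx(-3.0, abs=1e-5)

    def test_center_accepted_with_full_score(self, meb_table, linear):
        m = fit(meb_table, SampleWeights(np.ones(3)), C=10.0, kernel=linear)
        acc, score = predict_membership(
            m, FeatureTable(["z"], ["?"], np.array([[1.0, 0.0]]))
        )
        assert acc[0] and score[0] == pytest.approx(1.0, abs=1e-5)

    def test_dimension_mismatch(self, meb_table, linear):
        m = fit(meb_table, SampleWeights(np.ones(3)), C=10.0, kernel=linear)
        with pytest.raises(ValueError, match="dimension"):
            squared_center_distance(m, [1.0, 2.0, 3.0])


class TestVariants:
    def test_ocsvm_and_svdd_agree_on_rbf_decisions(self, rng, rbf_half):
        X = rng.standard_normal((25, 3))
        t = FeatureTable([str(i) for i in range(25)], ["x"] * 25, X)
        Z = FeatureTable(
            [f"z{i}" for i in range(40)], ["?"] * 40, rng.standard_normal((40, 3)) * 2
        )
        for C in [0.2, 0.5, 5.0]:
            a1, _ = predict_membership(fit_oneclass(t, C, rbf_half, "ocsvm"), Z)
            a2, _ = predict_membership(fit_oneclass(t, C, rbf_half, "svdd"), Z)
            assert np.array_equal(a1, a2)

    def test_weighting_rejects_outlier_at_larger_C(self):
        """With an outlier in training, the weighted sphere stops covering
        the outlier's location at a larger C (i.e. earlier in a C sweep)
        than the unweighted sphere does."""
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0.0, 0.3, size=19), [5.0]])[:, None]
        t = FeatureTable([str(i) for i in range(20)], ["x"] * 20, x)
        probe = FeatureTable(["p"], ["?"], np.array([[5.0]]))
        kernel = KernelSpec("rbf", 0.5)
        sweep = np.linspace(1.0, 0.055, 30)
        first_reject = {}
        for variant in ("wsvdd", "svdd"):
            first_reject[variant] = None
            for C in sweep:
                acc, _ = predict_membership(fit_oneclass(t, C, kernel, variant), probe)
                if not acc[0]:
                    first_reject[variant] = C
                    break
        assert first_reject["wsvdd"] is not None
        assert (
            first_reject["svdd"] is None
            or first_reject["wsvdd"] > first_reject["svdd"]
        )

    def test_unknown_variant_errors(self, meb_table, rbf_half):
        with pytest.raises(ValueError, match="variant"):
            fit_oneclass(meb_table, 1.0, rbf_half, variant="bayes")


class TestSerialization:
    def test_round_trip_preserves_decisions_bit_exactly(self, rng, rbf_half):
        X = rng.standard_normal((15, 3))
        t = FeatureTable([str(i) for i in range(15)], ["x"] * 15, X)
        m = fit_oneclass(t, C=0.4, kernel=rbf_half, variant="wsvdd")
        m2 = model_from_json(model_to_json(m))
        assert np.array_equal(m.alphas, m2.alphas)
        assert np.array_equal(m.sv_rows, m2.sv_rows)
        assert m.r2 == m2.r2 and m.center_term == m2.center_term
        Z = FeatureTable([f"z{i}" for i in range(30)], ["?"] * 30,
                         rng.standard_normal((30, 3)) * 2)
        a1, s1 = predict_membership(m, Z)
        a2, s2 = predict_membership(m2, Z)
        assert np.array_equal(a1, a2) and np.array_equal(s1, s2)
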
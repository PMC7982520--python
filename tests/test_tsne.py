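"""t-SNE core: affinity calibration, cost/gradient exactness, optimization."""

import numpy as np
import pytest

from erpdecode import tsne
from erpdecode.tsne import (
    AffinityMatrix,
    DatapointMatrix,
    conditional_affinities,
    kl_cost,
    kl_gradient,
    low_dim_affinities,
    run_tsne,
    symmetrize,
)


def _entropy_perplexity(row):
    p = row[row > 0]
    return 2.0 ** (-np.sum(p * np.log2(p)))


class TestConditionalAffinities:
    def test_diagonal_zero_rows_normalized(self, rng):
        X = rng.standard_normal((25, 8))
        aff = conditional_affinities(X, perplexity=7)
        assert np.all(np.diag(aff.P) == 0.0)
        np.testing.assert_allclose(aff.P.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(aff.P >= 0)

    def test_three_equidistant_points(self):
        # three unit basis vectors are mutually equidistant (all pairs at
        # sqrt(2) exactly), so symmetry forces every conditional onto 1/2
        X = np.eye(3)
        aff = conditional_affinities(X, perplexity=1.5)
        off = aff.P[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.5, atol=1e-8)

    def test_perplexity_recovered_per_row(self, rng):
        # independent oracle: recompute 2^H from the returned rows
        X = rng.standard_normal((60, 10))
        aff = conditional_affinities(X, perplexity=10)
        for row in aff.P:
            assert abs(_entropy_perplexity(row) - 10.0) < 1e-4

    def test_duplicate_rows_stay_finite(self, rng):
        X = rng.standard_normal((20, 5))
        X[3] = X[7]
        X[12] = X[7]
        aff = conditional_affinities(X, perplexity=5)
        assert np.all(np.isfinite(aff.P))
        np.testing.assert_allclose(aff.P.sum(axis=1), 1.0, atol=1e-8)

    def test_perplexity_clamped_for_small_n(self, rng):
        X = rng.standard_normal((10, 4))
        aff = conditional_affinities(X, perplexity=50)
        assert aff.perplexity == pytest.approx(3.0)  # (n - 1) / 3

    def test_sigma_scales_with_data(self, rng):
        X = rng.standard_normal((30, 6))
        a1 = conditional_affinities(X, perplexity=8)
        a2 = conditional_affinities(10.0 * X, perplexity=8)
        np.testing.assert_allclose(a2.sigmas / a1.sigmas, 10.0, rtol=1e-3)


class TestSymmetrize:
    def test_joint_properties(self, rng):
        X = rng.standard_normal((30, 5))
        joint = symmetrize(conditional_affinities(X, 8))
        assert joint.mode == "joint"
        np.testing.assert_array_equal(joint.P, joint.P.T)
        assert joint.P.sum() == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_input_fixed_point(self):
        P = np.array([[0.0, 0.4, 0.6], [0.4, 0.0, 0.6], [0.6, 0.4, 0.0]])
        P = (P + P.T) / 2
        P /= P.sum(axis=1, keepdims=True)
        # if the conditional matrix is already symmetric the joint is P / n
        P_sym = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        aff = AffinityMatrix(P=P_sym, perplexity=2, mode="conditional")
        joint = symmetrize(aff)
        np.testing.assert_allclose(joint.P, P_sym / 3.0, atol=1e-15)

    def test_joint_input_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        joint = symmetrize(conditional_affinities(X, 3))
        with pytest.raises(ValueError):
            symmetrize(joint)


class TestLowDimAffinities:
    def test_two_points_joint(self):
        Y = np.array([[0.0, 0.0], [3.0, 4.0]])
        q = low_dim_affinities(Y).P
        np.testing.assert_allclose(q[0, 1], 0.5)
        np.testing.assert_allclose(q[1, 0], 0.5)

    def test_kernel_maximum_at_zero_distance(self, rng):
        Y = rng.standard_normal((10, 3))
        Y[4] = Y[7]
        W = tsne._student_t_weights(Y)
        assert W[4, 7] == pytest.approx(1.0)
        assert W.max() == pytest.approx(1.0)

    def test_matches_double_loop(self, rng):
        Y = rng.standard_normal((12, 4))
        got = low_dim_affinities(Y).P
        # brute-force double loop
        W = np.zeros((12, 12))
        for i in range(12):
            for j in range(12):
                if i != j:
                    W[i, j] = 1.0 / (1.0 + np.sum((Y[i] - Y[j]) ** 2))
        expect = W / W.sum()
        np.testing.assert_allclose(got, expect, atol=1e-12)


class TestKlCost:
    def test_identity_and_nonnegativity(self, rng):
        X = rng.standard_normal((15, 4))
        P = symmetrize(conditional_affinities(X, 4))
        assert kl_cost(P, P) == pytest.approx(0.0, abs=1e-12)
        Q = low_dim_affinities(rng.standard_normal((15, 2)))
        assert kl_cost(P, Q) >= 0.0

    def test_matches_double_loop(self, rng):
        X = rng.standard_normal((10, 3))
        P = symmetrize(conditional_affinities(X, 3))
        Q = low_dim_affinities(rng.standard_normal((10, 2)))
        expect = 0.0
        for i in range(10):
            for j in range(10):
                if P.P[i, j] > 0:
                    expect += P.P[i, j] * np.log(P.P[i, j] / max(Q.P[i, j], 1e-12))
        assert kl_cost(P, Q) == pytest.approx(expect, abs=1e-12)

    def test_shape_and_mode_mismatch(self, rng):
        X = rng.standard_normal((8, 3))
        P = symmetrize(conditional_affinities(X, 2))
        with pytest.raises(ValueError):
            kl_cost(P, low_dim_affinities(rng.standard_normal((9, 2))))
        with pytest.raises(ValueError):
            kl_cost(P, low_dim_affinities(rng.standard_normal((8, 2)), mode="conditional"))


class TestKlGradient:
    @pytest.mark.parametrize("variant", ["joint", "conditional"])
    def test_finite_difference_agreement(self, rng, variant):
        # the binding correctness contract for whichever cost is configured
        n, d = 20, 3
        X = rng.standard_normal((n, 6))
        cond = conditional_affinities(X, 6)
        P = symmetrize(cond) if variant == "joint" else cond
        Y = rng.standard_normal((n, d))
        grad = kl_gradient(P, Y, variant=variant)
        eps = 1e-6
        for i in range(0, n, 5):
            for k in range(d):
                Yp, Ym = Y.copy(), Y.copy()
                Yp[i, k] += eps
                Ym[i, k] -= eps
                c_p = kl_cost(P, low_dim_affinities(Yp, mode=P.mode))
                c_m = kl_cost(P, low_dim_affinities(Ym, mode=P.mode))
                fd = (c_p - c_m) / (2 * eps)
                assert abs(grad[i, k] - fd) <= 1e-4 * max(1.0, abs(fd))

    def test_zero_at_matching_distribution(self):
        # Q(Y) == P exactly when P is built from the same Student-t kernel
        rng = np.random.default_rng(5)
        Y = rng.standard_normal((12, 2))
        Q = low_dim_affinities(Y)
        grad = kl_gradient(Q, Y, variant="joint")
        np.testing.assert_allclose(grad, 0.0, atol=1e-8)

    def test_translation_invariance(self, rng):
        X = rng.standard_normal((15, 5))
        P = symmetrize(conditional_affinities(X, 4))
        grad = kl_gradient(P, rng.standard_normal((15, 3)))
        np.testing.assert_allclose(grad.sum(axis=0), 0.0, atol=1e-10)


class TestRunTsne:
    def test_output_dims_and_determinism(self, rng):
        X = rng.standard_normal((30, 12))
        emb1 = run_tsne(X, dims=5, perplexity=8, iterations=60, seed=3)
        emb2 = run_tsne(X, dims=5, perplexity=8, iterations=60, seed=3)
        assert emb1.Y.shape == (30, 5)
        np.testing.assert_array_equal(emb1.Y, emb2.Y)  # bitwise
        np.testing.assert_array_equal(emb1.cost_trace, emb2.cost_trace)

    def test_cluster_geometry_recovered(self, rng):
        # two well-separated Gaussian clusters separate in the embedding
        A = rng.normal(0.0, 1.0, (30, 10))
        B = rng.normal(12.0, 1.0, (30, 10))
        emb = run_tsne(np.vstack([A, B]), dims=2, perplexity=10,
                       iterations=400, seed=0)
        Y = emb.Y
        between = np.linalg.norm(Y[:30].mean(axis=0) - Y[30:].mean(axis=0))
        within = 0.5 * (
            np.linalg.norm(Y[:30] - Y[:30].mean(axis=0), axis=1).mean()
            + np.linalg.norm(Y[30:] - Y[30:].mean(axis=0), axis=1).mean()
        )
        assert between > within

    def test_cost_nonincreasing_at_small_steps(self):
        # statistical property over seeds, exaggeration and gains disabled
        violations = 0
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            X = rng.standard_normal((25, 6))
            emb = run_tsne(X, dims=2, perplexity=6, iterations=120,
                           learning_rate=1.0, seed=seed, early_exaggeration=1.0,
                           exaggeration_iters=0, use_gains=False)
            trace = emb.cost_trace[10:]
            violations += int(np.any(np.diff(trace) > 1e-9))
        assert violations == 0
        assert np.all(emb.cost_trace >= 0)

    def test_affinity_permutation_equivariance(self, rng):
        # permuting the datapoints permutes both axes of P (and the sigmas);
        # the stochastic initialization ties the embedding itself to row order
        X = rng.standard_normal((16, 5))
        perm = rng.permutation(16)
        P = symmetrize(conditional_affinities(X, 4)).P
        Pp = symmetrize(conditional_affinities(X[perm], 4)).P
        np.testing.assert_allclose(Pp, P[np.ix_(perm, perm)], atol=1e-12)

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            run_tsne(np.full((10, 3), np.nan))
        with pytest.raises(ValueError):
            run_tsne(rng.standard_normal((3, 3)))

    def test_fused_kernels_match_reference_formulas(self, rng):
        # the numba fast path must compute the same gradient and cost terms
        # as the plain formulas (trajectories diverge only through fp noise)
        if tsne._numba is None:
            pytest.skip("numba unavailable")
        X = rng.standard_normal((40, 8))
        P = symmetrize(conditional_affinities(X, 8))
        Y = rng.standard_normal((40, 3))
        grad_fused = np.empty_like(Y)
        tsne._fused_joint_grad(Y, P.P, grad_fused)
        np.testing.assert_allclose(grad_fused, kl_gradient(P, Y), atol=1e-10)
        plogq = tsne._fused_joint_plogq(Y, P.P, 1e-12)
        Q = low_dim_affinities(Y)
        mask = P.P > 0
        expect = float(np.sum(P.P[mask] * np.log(Q.P[mask])))
        assert plogq == pytest.approx(expect, rel=1e-10)


class TestDatapointMatrix:
    def test_validation(self, rng):
        with pytest.raises(ValueError):
            DatapointMatrix(X=rng.standard_normal(5))
        with pytest.raises(ValueError):
            DatapointMatrix(X=np.full((4, 4), np.inf))
        with pytest.raises(ValueError):
            DatapointMatrix(X=rng.standard_normal((1, 4)))
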
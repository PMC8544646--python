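import numpy as np
import pytest

from mvpac.horpca import (
    default_lambda,
    horpca_singleton,
    mode_fold,
    mode_unfold,
    soft_threshold,
    svt,
)


@pytest.fixture
def rank1_tensor(rng):
    """Incoherent nonnegative rank-1 tensor (exact-recovery regime)."""
    vs = [0.5 + rng.random(s) for s in (6, 6, 4, 5)]
    return np.einsum("i,j,k,l->ijkl", *vs)


class TestUnfolding:
    @pytest.mark.parametrize("n", range(4))
    def test_fold_inverts_unfold(self, rng, n):
        X = rng.standard_normal((3, 4, 2, 2))
        assert np.array_equal(mode_fold(mode_unfold(X, n), n, X.shape), X)

    def test_rank1_unfoldings_have_rank_one(self, rng):
        vs = [rng.standard_normal(s) for s in (3, 4, 2, 2)]
        X = np.einsum("i,j,k,l->ijkl", *vs)
        for n in range(4):
            s = np.linalg.svd(mode_unfold(X, n), compute_uv=False)
            assert s[1] < 1e-10 * s[0]

    def test_hand_enumerated_fibers(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        # mode-0 fibers are columns of X; mode-1 fibers are rows
        assert np.array_equal(mode_unfold(X, 0), X)
        assert np.array_equal(mode_unfold(X, 1), X.T)

    def test_bad_mode(self, rng):
        X = rng.standard_normal((2, 2, 2))
        with pytest.raises(ValueError):
            mode_unfold(X, 3)
        with pytest.raises(ValueError):
            mode_fold(np.zeros((2, 4)), 5, (2, 2, 2))


class TestProximalOperators:
    def test_svt_tau_zero_identity(self, rng):
        M = rng.standard_normal((5, 4))
        assert np.allclose(svt(M, 0.0), M)

    def test_svt_large_tau_zeroes(self, rng):
        M = rng.standard_normal((5, 4))
        sigma_max = np.linalg.norm(M, ord=2)
        assert np.allclose(svt(M, sigma_max + 1), 0.0)

    def test_svt_matches_svd_oracle(self, rng):
        M = rng.standard_normal((5, 4))
        u, s, vt = np.linalg.svd(M, full_matrices=False)
        expected = u @ np.diag(np.maximum(s - 0.5, 0.0)) @ vt
        assert np.allclose(svt(M, 0.5), expected, atol=1e-8)

    def test_svt_scale_equivariance(self, rng):
        M = rng.standard_normal((4, 4))
        c = 3.7
        assert np.allclose(svt(c * M, c * 0.4), c * svt(M, 0.4), atol=1e-10)

    def test_soft_threshold_identity(self, rng):
        X = rng.standard_normal((3, 3, 3))
        assert np.allclose(soft_threshold(X, 0.0), X)

    def test_soft_threshold_all_zero(self, rng):
        X = 0.1 * rng.standard_normal((3, 3))
        assert np.all(soft_threshold(X, 1.0) == 0)

    def test_soft_threshold_scalar_oracle(self, rng):
        X = rng.standard_normal(50)
        tau = 0.3
        expected = np.array(
            [np.sign(x) * max(abs(x) - tau, 0.0) for x in X]
        )
        assert np.allclose(soft_threshold(X, tau), expected)

    def test_soft_threshold_scale_equivariance(self, rng):
        X = rng.standard_normal(20)
        c = 2.5
        assert np.allclose(
            soft_threshold(c * X, c * 0.3), c * soft_threshold(X, 0.3)
        )

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            svt(np.eye(2), -1.0)
        with pytest.raises(ValueError):
            soft_threshold(np.eye(2), -1.0)


class TestDefaultLambda:
    def test_examples(self):
        assert default_lambda((64, 64, 4, 20)) == pytest.approx(0.125)
        assert default_lambda((4, 4, 4, 4)) == pytest.approx(0.5)

    def test_literal_reading(self):
        assert default_lambda((64, 64, 4, 20), literal=True) == pytest.approx(1 / 64)

    def test_monotone_in_imax(self):
        lams = [default_lambda((n, n, 4, 5)) for n in (4, 9, 16, 25, 64)]
        assert all(a >= b for a, b in zip(lams, lams[1:]))


class TestHoRPCA:
    def test_exact_rank1_recovery(self, rank1_tensor):
        d = horpca_singleton(rank1_tensor, warn=False)
        assert d.converged
        assert np.linalg.norm(d.sparse) / np.linalg.norm(rank1_tensor) < 1e-3
        assert (
            np.linalg.norm(d.low_rank - rank1_tensor)
            / np.linalg.norm(rank1_tensor)
            < 1e-2
        )

    def test_planted_support_recovery(self, rank1_tensor, rng):
        S0 = np.zeros_like(rank1_tensor)
        idx = rng.choice(rank1_tensor.size, 5, replace=False)
        S0.flat[idx] = 10 * rank1_tensor.max()
        d = horpca_singleton(rank1_tensor + S0, max_iter=1000, warn=False)
        top = np.argsort(np.abs(d.sparse).ravel())[-5:]
        assert sorted(top.tolist()) == sorted(idx.tolist())

    def test_feasibility_at_convergence(self, rank1_tensor, rng):
        A = rank1_tensor + 0.01 * rng.random(rank1_tensor.shape)
        d = horpca_singleton(A, tol=1e-6, max_iter=2000, warn=False)
        if d.converged:
            assert (
                np.linalg.norm(A - d.low_rank - d.sparse) / np.linalg.norm(A)
                <= 1e-5
            )

    def test_lambda_extremes(self, rng):
        A = np.abs(rng.standard_normal((6, 6, 4, 5)))
        d_hi = horpca_singleton(A, lam=100.0, max_iter=300, warn=False)
        assert np.linalg.norm(d_hi.sparse) / np.linalg.norm(A) < 1e-6
        d_lo = horpca_singleton(A, lam=1e-4, max_iter=300, warn=False)
        assert np.linalg.norm(d_lo.low_rank) / np.linalg.norm(A) < 0.05

    def test_sparsity_monotone_in_lambda(self, rng):
        A = np.abs(rng.standard_normal((8, 8, 4, 6)))
        nnz = [
            np.count_nonzero(
                horpca_singleton(A, lam=lam, max_iter=300, warn=False).sparse
            )
            for lam in (0.05, 0.1, 0.2, 0.4, 0.8)
        ]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_fixed_point_residual_decays(self, rank1_tensor, rng):
        """The ADAL iterate-change residual decays to convergence.

        Strict per-step monotonicity does not hold for the (L, S) block of
        the splitting (tiny oscillations appear near the fixed point), so the
        asserted property is a large overall decay plus a bounded tail.
        """
        S0 = np.zeros_like(rank1_tensor)
        S0.flat[rng.choice(rank1_tensor.size, 5, replace=False)] = (
            10 * rank1_tensor.max()
        )
        d = horpca_singleton(
            rank1_tensor + S0, max_iter=1000, warn=False, track_objective=True
        )
        fp = d.fixed_point_history
        assert len(fp) > 5
        assert fp[-1] < 1e-3 * fp[:3].max()
        running_min = np.minimum.accumulate(fp)
        assert np.all(fp[5:] <= 100 * running_min[5:] + 1e-12)

    def test_objective_converges(self, rank1_tensor, rng):
        d = horpca_singleton(
            rank1_tensor, warn=False, track_objective=True, max_iter=500
        )
        obj = d.objective_history
        # relative objective change vanishes by the end of the run
        tail = np.abs(np.diff(obj))[-3:] / max(obj[-1], 1e-12)
        assert tail.max() < 1e-4

    def test_zero_tensor(self):
        d = horpca_singleton(np.zeros((3, 3, 3)), warn=False)
        assert d.converged
        assert np.all(d.sparse == 0) and np.all(d.low_rank == 0)

    def test_nonfinite_rejected(self):
        A = np.ones((3, 3, 3))
        A[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            horpca_singleton(A)

    def test_nonconvergence_warns(self, rank1_tensor):
        with pytest.warns(RuntimeWarning):
            d = horpca_singleton(rank1_tensor + 0.5, max_iter=3, tol=1e-14)
        assert not d.converged
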
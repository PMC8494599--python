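import numpy as np
import pytest
import scipy.linalg

from latfuse import (
    SolverConfig,
    decompose_multi,
    make_lowrank_sparse,
    soft_threshold,
    solve_latlrr,
    svt,
)
from latfuse.phantoms import PhantomSpec, make_structural_phantom


def brute_soft_threshold(M, tau):
    """Independent elementwise shrinkage: explicit branching per entry."""
    out = np.empty_like(M, dtype=float)
    for i in range(M.shape[0]):
        for j in range(M.shape[1]):
            m = M[i, j]
            if m > tau:
                out[i, j] = m - tau
            elif m < -tau:
                out[i, j] = m + tau
            else:
                out[i, j] = 0.0
    return out


def brute_svt(M, tau):
    """Independent nuclear-norm prox: full scipy SVD, explicit reconstruction."""
    U, s, Vt = scipy.linalg.svd(M, full_matrices=True)
    out = np.zeros_like(M, dtype=float)
    for k in range(len(s)):
        sk = s[k] - tau
        if sk > 0:
            out += sk * np.outer(U[:, k], Vt[k, :])
    return out


class TestProxOperators:
    def test_soft_threshold_pointwise_examples(self):
        assert soft_threshold(np.array([[0.5]]), 0.2)[0, 0] == pytest.approx(0.3)
        assert soft_threshold(np.array([[-0.1]]), 0.2)[0, 0] == 0.0

    def test_soft_threshold_zero_tau_is_identity(self, rng):
        M = rng.standard_normal((6, 4))
        assert np.array_equal(soft_threshold(M, 0.0), M)

    def test_soft_threshold_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.zeros((2, 2)), -0.1)

    def test_svt_diagonal_example(self):
        out = svt(np.diag([3.0, 1.0]), 2.0)
        assert np.allclose(out, np.diag([1.0, 0.0]), atol=1e-12)

    def test_svt_zero_tau_reproduces_input(self, rng):
        M = rng.standard_normal((5, 7))
        assert np.abs(svt(M, 0.0) - M).max() < 1e-12

    def test_svt_rejects_non_finite(self):
        with pytest.raises(Exception):
            svt(np.array([[np.nan, 0.0], [0.0, 1.0]]), 0.5)

    def test_prox_operators_match_brute_force_on_seeded_matrices(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            M = rng.standard_normal((5, 5))
            tau = rng.uniform(0.0, 1.5)
            assert np.abs(soft_threshold(M, tau) - brute_soft_threshold(M, tau)).max() < 1e-10
            assert np.abs(svt(M, tau) - brute_svt(M, tau)).max() < 1e-10

    def test_svt_minimizes_the_proximal_objective(self, rng):
        """The SVT output should beat random perturbations on the objective."""
        M = rng.standard_normal((5, 5))
        tau = 0.7
        Y = svt(M, tau)

        def objective(A):
            return tau * np.linalg.svd(A, compute_uv=False).sum() + 0.5 * np.linalg.norm(A - M) ** 2

        base = objective(Y)
        for _ in range(20):
            assert base <= objective(Y + 1e-3 * rng.standard_normal((5, 5))) + 1e-12


class TestSolver:
    def test_zero_input_gives_zero_components(self):
        comp = solve_latlrr(np.zeros((8, 8)))
        assert np.all(comp.Z == 0) and np.all(comp.L == 0) and np.all(comp.E == 0)
        assert comp.residual == 0.0
        assert comp.converged

    def test_constraint_holds_at_convergence(self, phantom64):
        cfg = SolverConfig()
        comp = solve_latlrr(phantom64, cfg)
        assert comp.converged
        gap = phantom64 - comp.lowrank_part - comp.saliency_part - comp.E
        assert np.linalg.norm(gap) / np.linalg.norm(phantom64) < cfg.tol

    def test_component_shapes(self, phantom64):
        comp = solve_latlrr(phantom64[:, :48])
        assert comp.Z.shape == (48, 48)
        assert comp.L.shape == (64, 64)
        assert comp.E.shape == (64, 48)

    def test_deterministic_bitwise(self, phantom64):
        c1 = solve_latlrr(phantom64)
        c2 = solve_latlrr(phantom64)
        assert np.array_equal(c1.Z, c2.Z)
        assert np.array_equal(c1.L, c2.L)
        assert np.array_equal(c1.E, c2.E)

    def test_lowrank_sparse_recovery(self):
        """With the robust-PCA balance lam=1/sqrt(n), the sparse spikes land in E
        and XZ stays near the planted rank."""
        X, G, S = make_lowrank_sparse(64, 2, 0.02, seed=3)
        comp = solve_latlrr(X, SolverConfig(lam=1 / 8))
        assert np.linalg.norm(comp.E - S) / np.linalg.norm(S) < 0.25
        sv = np.linalg.svd(comp.lowrank_part, compute_uv=False)
        assert int(np.sum(sv > 0.01 * sv[0])) <= 6

    def test_large_lambda_prices_out_the_sparse_part(self):
        """A huge l1 price must empty E; probed with the slow high-accuracy
        penalty ramp, since the fast default ramp can freeze the split
        before the l1 cost fully acts."""
        rng = np.random.default_rng(17)
        X = rng.uniform(0, 1, (48, 48))
        comp = solve_latlrr(X, SolverConfig(lam=1e3, rho=1.02, max_iter=4000))
        assert np.linalg.norm(comp.E) / np.linalg.norm(X) < 1e-3

    def test_solver_config_validation(self):
        with pytest.raises(ValueError):
            SolverConfig(lam=0)
        with pytest.raises(ValueError):
            SolverConfig(rho=0.9)
        with pytest.raises(ValueError):
            SolverConfig(mu0=1.0, mu_max=0.1)


class TestMultiLayer:
    @pytest.mark.parametrize("n_layers", [1, 2, 3])
    def test_telescoping_conservation(self, phantom64, n_layers):
        cfg = SolverConfig()
        stack = decompose_multi(phantom64, n_layers, cfg)
        assert stack.layers == n_layers
        err = np.linalg.norm(stack.reconstruct() - phantom64) / np.linalg.norm(phantom64)
        assert err <= n_layers * cfg.tol

    def test_deeper_terminal_is_smoother(self):
        """High-frequency (Laplacian) energy of the terminal low-rank part
        should not grow as more saliency layers are peeled off."""
        from scipy import ndimage

        ph = make_structural_phantom(PhantomSpec(size=(64, 64), seed=4))
        e1 = np.linalg.norm(ndimage.laplace(decompose_multi(ph, 1).lowrank_terminal))
        e3 = np.linalg.norm(ndimage.laplace(decompose_multi(ph, 3).lowrank_terminal))
        assert e3 <= e1

    def test_invalid_layer_count(self, phantom64):
        with pytest.raises(ValueError):
            decompose_multi(phantom64, 0)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        M=arrays(np.float64, (4, 4), elements=st.floats(-10, 10)),
        tau=st.floats(0, 5),
    )
    def test_soft_threshold_shrinks_toward_zero(M, tau):
        """Shrinkage never flips signs, never grows magnitudes, and zeroes
        everything at or below the threshold."""
        out = soft_threshold(M, tau)
        assert np.all(np.abs(out) <= np.abs(M))
        assert np.all(out * M >= 0)
        assert np.all(out[np.abs(M) <= tau] == 0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(M=arrays(np.float64, (4, 5), elements=st.floats(-5, 5)), tau=st.floats(0, 3))
    def test_svt_never_increases_singular_values(M, tau):
        s_in = np.linalg.svd(M, compute_uv=False)
        s_out = np.linalg.svd(svt(M, tau), compute_uv=False)
        assert np.all(s_out <= s_in + 1e-9)
        assert np.all(s_out <= np.maximum(s_in - tau, 0.0) + 1e-9)
except ImportError:  # hypothesis is an optional test dependency
    pass
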
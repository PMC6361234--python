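import logging

import numpy as np
import pytest

from smssvd import (
    DataMatrix,
    SelectionMap,
    SignalFactors,
    SMSSVDConfig,
    SubspaceBasis,
    concatenate_signals,
    generate_dataset,
    greedy_match,
    reconstruct,
    remove_signal,
    restricted_svd,
    select_expand,
    smssvd,
    SyntheticConfig,
)
from smssvd.exceptions import (
    DimensionError,
    OrthogonalityError,
    RankError,
    ShapeError,
)
from tutils import random_datamatrix, rank_oracle, rowspace_basis, svd_oracle


class TestRestrictedSVD:
    def test_full_basis_recovers_svd(self):
        x = random_datamatrix(4, 3, seed=1)
        factors = restricted_svd(x, SubspaceBasis(np.eye(3)))
        u, s, vt = svd_oracle(x.values)
        np.testing.assert_allclose(factors.sigma, s, atol=1e-12)
        for j in range(3):
            sign = np.sign(factors.U[:, j] @ u[:, j])
            np.testing.assert_allclose(factors.U[:, j], sign * u[:, j], atol=1e-10)
            np.testing.assert_allclose(factors.V[:, j], sign * vt[j], atol=1e-10)

    def test_axis_aligned_restriction(self):
        x = DataMatrix(np.diag([3.0, 2.0]))
        factors = restricted_svd(x, SubspaceBasis(np.array([[1.0], [0.0]])))
        np.testing.assert_allclose(factors.U, [[1.0], [0.0]], atol=1e-14)
        np.testing.assert_allclose(factors.sigma, [3.0])
        np.testing.assert_allclose(factors.V, [[1.0], [0.0]], atol=1e-14)

    def test_top_right_singular_subspace_gives_truncated_svd(self):
        x = random_datamatrix(6, 4, seed=7)
        u, s, vt = svd_oracle(x.values)
        factors = restricted_svd(x, SubspaceBasis(vt[:2].T))
        np.testing.assert_allclose(factors.sigma, s[:2], atol=1e-10)
        np.testing.assert_allclose(
            x.values @ factors.V, factors.U * factors.sigma, atol=1e-10
        )
        recon = factors.matrix()
        oracle = (u[:, :2] * s[:2]) @ vt[:2]
        np.testing.assert_allclose(recon, oracle, atol=1e-10)

    def test_kernel_intersection_rejected(self):
        # rank-1 matrix: any basis vector orthogonal to its row space is in ker
        u_vec = np.ones((4, 1))
        v_vec = np.array([1.0, 0.0, 0.0])
        x = DataMatrix(u_vec * v_vec)
        basis = SubspaceBasis(np.array([[0.0], [1.0], [0.0]]))
        with pytest.raises(RankError):
            restricted_svd(x, basis)

    def test_ambient_mismatch_rejected(self):
        x = random_datamatrix(4, 3, seed=0)
        with pytest.raises(ShapeError):
            restricted_svd(x, SubspaceBasis(np.eye(4)[:, :2]))


@pytest.mark.parametrize("p,n,rank", [(5, 5, 5), (8, 4, 4), (4, 8, 4),
                                      (10, 6, 3), (6, 10, 4), (30, 7, 7)])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_decomposition_theorem_properties(p, n, rank, seed):
    """X V = U S; factor orthonormality; residual projection identity;
    rank additivity -- for random X and random subspaces of the row space."""
    x = random_datamatrix(p, n, seed=seed, rank=None if rank == min(p, n) else rank)
    r = rank_oracle(x.values)
    rng = np.random.default_rng(seed + 100)
    d = int(rng.integers(1, r + 1))
    basis = rowspace_basis(x.values, d, seed + 200)
    f = restricted_svd(x, SubspaceBasis(basis))

    np.testing.assert_allclose(x.values @ f.V, f.U * f.sigma, atol=1e-10)
    np.testing.assert_allclose(f.U.T @ f.U, np.eye(d), atol=1e-10)
    np.testing.assert_allclose(f.V.T @ f.V, np.eye(d), atol=1e-10)
    # columns of V lie in the row space (perp to ker X), U in the column space
    _, _, vt = svd_oracle(x.values)
    u_full, _, _ = svd_oracle(x.values)
    np.testing.assert_allclose(vt[r:] @ f.V, 0, atol=1e-8)
    np.testing.assert_allclose(u_full[:, r:].T @ f.U, 0, atol=1e-8)
    # V spans the requested subspace exactly
    np.testing.assert_allclose(
        f.V @ (f.V.T @ basis), basis, atol=1e-10
    )
    # (I - UU^T) X (I - VV^T) = (I - UU^T) X
    left = x.values - f.U @ (f.U.T @ x.values)
    right = left - (left @ f.V) @ f.V.T
    np.testing.assert_allclose(right, left, atol=1e-10)
    # rank additivity (rank measured against the original scale)
    smax = np.linalg.svd(x.values, compute_uv=False)[0]
    assert rank_oracle(left, rtol=1e-10, ref=smax) == r - d


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_selection_expansion_theorem_properties(seed):
    rng = np.random.default_rng(seed)
    p, n = 12, 7
    x = random_datamatrix(p, n, seed=seed + 10)
    size = int(rng.integers(2, p + 1))
    sel = SelectionMap.subset(
        np.sort(rng.choice(p, size=size, replace=False)), n_variables=p
    )
    sub = sel.apply(x.values)
    u_t, s_t, vt_t = svd_oracle(sub)
    max_d = rank_oracle(sub)
    for d in range(1, max_d + 1):
        f = select_expand(x, sel, d)
        # property 2: S^T U S V^T equals the truncated submatrix SVD
        lhs = sel.apply(f.matrix())
        rhs = (u_t[:, :d] * s_t[:d]) @ vt_t[:d]
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)
        # property 3: span(V) == span(V~) (principal angles ~ 0)
        overlap = np.linalg.svd(vt_t[:d] @ f.V, compute_uv=False)
        np.testing.assert_allclose(overlap, np.ones(d), atol=1e-8)
        # property 5 / corollary: expansion grows the Frobenius mass
        assert np.linalg.norm(f.sigma) >= np.linalg.norm(f.submatrix_sigma) - 1e-10
        np.testing.assert_allclose(f.submatrix_sigma, s_t[:d], atol=1e-10)
        # property 6: U^T X = S V^T + U^T (I - SS^T) X (I - VV^T)
        s_dense = sel.matrix()
        residual = (
            f.U.T
            @ (np.eye(p) - s_dense @ s_dense.T)
            @ x.values
            @ (np.eye(n) - f.V @ f.V.T)
        )
        np.testing.assert_allclose(
            f.U.T @ x.values, np.diag(f.sigma) @ f.V.T + residual, atol=1e-8
        )


class TestSelectExpand:
    def test_identity_selection_is_truncated_svd(self):
        x = random_datamatrix(9, 5, seed=3)
        f = select_expand(x, SelectionMap.all_variables(9), 2)
        u, s, vt = svd_oracle(x.values)
        np.testing.assert_allclose(f.sigma, s[:2], atol=1e-10)
        np.testing.assert_allclose(f.matrix(), (u[:, :2] * s[:2]) @ vt[:2], atol=1e-10)

    def test_subset_inverse_property(self):
        x = random_datamatrix(6, 4, seed=11)
        sel = SelectionMap.subset([0, 2, 4], n_variables=6)
        f = select_expand(x, sel, 1)
        sub = x.values[[0, 2, 4]]
        u_t, s_t, vt_t = svd_oracle(sub)
        np.testing.assert_allclose(
            f.matrix()[[0, 2, 4]], (u_t[:, :1] * s_t[:1]) @ vt_t[:1], atol=1e-8
        )
        assert np.linalg.norm(f.sigma) >= np.linalg.norm(f.submatrix_sigma)

    def test_insufficient_rank_rejected(self):
        x = DataMatrix(np.outer([1.0, 2.0, 3.0], [1.0, 1.0]))  # rank 1
        with pytest.raises(RankError, match="insufficient submatrix rank"):
            select_expand(x, SelectionMap.all_variables(3), 2)

    def test_weighted_selection(self):
        x = random_datamatrix(5, 4, seed=5)
        weights = np.array([1.0, 0.0, 2.0, 0.5, 0.0])
        sel = SelectionMap.from_weights(weights)
        f = select_expand(x, sel, 2)
        # Theorem property 5 in the general form: ||S||_2 * ||Sigma||_F >= ||Sigma~||_F
        assert (
            np.max(weights) * np.linalg.norm(f.sigma)
            >= np.linalg.norm(f.submatrix_sigma) - 1e-10
        )


class TestRemoveSignal:
    def test_removing_everything_leaves_zero(self):
        x = random_datamatrix(5, 3, seed=2)
        _, _, vt = svd_oracle(x.values)
        f = restricted_svd(x, SubspaceBasis(vt.T))
        out = remove_signal(x, f)
        np.testing.assert_allclose(out.values, 0, atol=1e-10)

    def test_empty_signal_is_identity(self):
        x = random_datamatrix(5, 3, seed=2)
        out = remove_signal(x, SignalFactors.empty(5, 3))
        np.testing.assert_array_equal(out.values, x.values)

    def test_rank_drops_by_d(self):
        x = random_datamatrix(10, 8, seed=4, rank=5)
        basis = rowspace_basis(x.values, 2, seed=44)
        f = restricted_svd(x, SubspaceBasis(basis))
        out = remove_signal(x, f)
        smax = np.linalg.svd(x.values, compute_uv=False)[0]
        assert rank_oracle(out.values, rtol=1e-10, ref=smax) == 3

    def test_idempotent(self):
        x = random_datamatrix(8, 6, seed=9)
        basis = rowspace_basis(x.values, 2, seed=90)
        f = restricted_svd(x, SubspaceBasis(basis))
        once = remove_signal(x, f)
        twice = remove_signal(once, f)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_both_sided_projection_identity(self):
        x = random_datamatrix(8, 6, seed=9)
        basis = rowspace_basis(x.values, 2, seed=91)
        f = restricted_svd(x, SubspaceBasis(basis))
        out = remove_signal(x, f).values
        np.testing.assert_allclose(
            out, out - (out @ f.V) @ f.V.T, atol=1e-10
        )

    def test_shape_mismatch(self):
        x = random_datamatrix(5, 3, seed=2)
        f = SignalFactors.empty(4, 3)
        with pytest.raises(ShapeError):
            remove_signal(x, f)


class TestSMSSVD:
    def test_disabled_selection_equals_truncated_svd(self):
        x = random_datamatrix(20, 10, seed=6)
        res = smssvd(x, 4, SMSSVDConfig(disable_selection=True))
        u, s, vt = svd_oracle(x.values)
        np.testing.assert_allclose(res.sigma, s[:4], atol=1e-10)
        for j in range(4):
            sign = np.sign(res.U[:, j] @ u[:, j])
            np.testing.assert_allclose(res.U[:, j], sign * u[:, j], atol=1e-8)
            np.testing.assert_allclose(res.V[:, j], sign * vt[j], atol=1e-8)

    def test_noiseless_planted_signals_recovered(self):
        ds = generate_dataset(
            SyntheticConfig(P=200, N=40, L=16, K=2, d=2, noise_support="none", seed=3)
        )
        res = smssvd(DataMatrix(ds.X), 4, SMSSVDConfig(seed=3))
        match = greedy_match(res.components(), ds.signals)
        for k, signal in enumerate(ds.signals):
            assert match.per_signal_error[k] <= 1e-8 * signal.strength

    def test_target_dim_above_rank_warns_and_truncates(self, caplog):
        x = random_datamatrix(8, 6, seed=12, rank=3)
        with caplog.at_level(logging.WARNING, logger="smssvd.decomposition"):
            res = smssvd(x, 5, SMSSVDConfig(disable_selection=True))
        assert res.total_dim == 3
        assert any("exceeds numerical rank" in r.message for r in caplog.records)

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            smssvd(DataMatrix(np.zeros((4, 3))), 2)

    def test_target_dim_out_of_range(self):
        x = random_datamatrix(5, 4, seed=0)
        with pytest.raises(DimensionError):
            smssvd(x, 5)
        with pytest.raises(DimensionError):
            smssvd(x, 0, SMSSVDConfig())

    def test_deterministic(self):
        x = random_datamatrix(40, 15, seed=8)
        res1 = smssvd(x, 4, SMSSVDConfig(seed=5))
        res2 = smssvd(x, 4, SMSSVDConfig(seed=5))
        np.testing.assert_array_equal(res1.U, res2.U)
        np.testing.assert_array_equal(res1.sigma, res2.sigma)
        np.testing.assert_array_equal(res1.V, res2.V)
        np.testing.assert_array_equal(res1.residual.values, res2.residual.values)

    def test_cross_signal_orthogonality_and_rank_bookkeeping(self):
        x = random_datamatrix(60, 20, seed=13)
        res = smssvd(x, 6, SMSSVDConfig(seed=13))
        d_total = res.total_dim
        assert d_total == 6
        np.testing.assert_allclose(res.U.T @ res.U, np.eye(d_total), atol=1e-8)
        np.testing.assert_allclose(res.V.T @ res.V, np.eye(d_total), atol=1e-8)
        smax = np.linalg.svd(x.values, compute_uv=False)[0]
        assert rank_oracle(res.residual.values, rtol=1e-10, ref=smax) == 20 - d_total

    def test_open_ended_mode_stops_on_noiseless_signal(self):
        ds = generate_dataset(
            SyntheticConfig(P=300, N=30, L=16, K=1, d=3, noise_support="none", seed=5)
        )
        res = smssvd(DataMatrix(ds.X), None, SMSSVDConfig(seed=5))
        assert res.total_dim >= 3
        np.testing.assert_allclose(res.residual.values, 0, atol=1e-8)

    def test_centering_flag(self):
        x = random_datamatrix(15, 8, seed=21)
        res = smssvd(x, 2, SMSSVDConfig(disable_selection=True, center_variables=True))
        centered = x.values - x.values.mean(axis=1, keepdims=True)
        _, s, _ = svd_oracle(centered)
        np.testing.assert_allclose(res.sigma, s[:2], atol=1e-10)


class TestConcatenateReconstruct:
    def _orthogonal_signals(self, seed=14):
        x = random_datamatrix(10, 6, seed=seed)
        u, s, vt = svd_oracle(x.values)
        f1 = SignalFactors(U=u[:, :3], sigma=s[:3], V=vt[:3].T, d=3)
        f2 = SignalFactors(U=u[:, 3:4], sigma=s[3:4], V=vt[3:4].T, d=1)
        return x, f1, f2

    def test_single_signal_wrapped_unchanged(self):
        x, f1, _ = self._orthogonal_signals()
        res = concatenate_signals([f1], x)
        np.testing.assert_array_equal(res.U, f1.U)
        np.testing.assert_array_equal(res.sigma, f1.sigma)
        assert res.total_dim == 3

    def test_concatenated_orthogonality_and_naive_sum(self):
        x, f1, f2 = self._orthogonal_signals()
        res = concatenate_signals([f1, f2], x)
        np.testing.assert_allclose(res.U.T @ res.U, np.eye(4), atol=1e-8)
        naive = f1.matrix() + f2.matrix()  # independent summation oracle
        np.testing.assert_allclose(reconstruct(res).values, naive, atol=1e-12)

    def test_empty_result_reconstructs_zero(self):
        x = random_datamatrix(4, 3, seed=1)
        res = concatenate_signals([], x)
        np.testing.assert_array_equal(reconstruct(res).values, np.zeros((4, 3)))

    def test_non_orthogonal_signals_rejected(self):
        x, f1, _ = self._orthogonal_signals()
        with pytest.raises(OrthogonalityError):
            concatenate_signals([f1, f1], x)

    def test_full_rank_reconstruction_equals_input(self):
        x = random_datamatrix(7, 5, seed=17)
        res = smssvd(x, 5, SMSSVDConfig(disable_selection=True))
        np.testing.assert_allclose(reconstruct(res).values, x.values, atol=1e-8)

    def test_noiseless_reconstruction_equals_signal_sum(self):
        ds = generate_dataset(
            SyntheticConfig(P=150, N=30, L=12, K=2, d=2, noise_support="none", seed=7)
        )
        res = smssvd(DataMatrix(ds.X), 4, SMSSVDConfig(seed=7))
        total = sum(s.Y for s in ds.signals)
        np.testing.assert_allclose(reconstruct(res).values, total, atol=1e-8)
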
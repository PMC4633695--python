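"""Multilinear PCA: unfolding, fitting, projection, truncated reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from nlmpca import (
    Volume,
    fit_mpca,
    mode_fold,
    mode_unfold,
    mpca_denoise,
    mpca_project,
)
from oracles import mode_scatter_eig


def _match_up_to_sign(A: np.ndarray, B: np.ndarray, atol: float) -> None:
    """Columns of A equal columns of B up to sign."""
    assert A.shape == B.shape
    for k in range(A.shape[1]):
        d_plus = np.abs(A[:, k] - B[:, k]).max()
        d_minus = np.abs(A[:, k] + B[:, k]).max()
        assert min(d_plus, d_minus) < atol


class TestModeUnfold:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        t=hnp.arrays(
            np.float64,
            st.tuples(
                st.integers(1, 5), st.integers(1, 5), st.integers(1, 5)
            ),
            elements=st.floats(-10, 10, allow_nan=False),
        ),
        mode=st.integers(1, 3),
    )
    def test_fold_inverts_unfold(self, t, mode):
        np.testing.assert_array_equal(
            mode_fold(mode_unfold(t, mode), mode, t.shape), t
        )

    def test_literal_index_loop_oracle(self):
        t = np.arange(1, 9, dtype=float).reshape(2, 2, 2)
        # mode-1 unfolding: rows i1, column index i2 * I3 + i3
        expected = np.empty((2, 4))
        for i1 in range(2):
            for i2 in range(2):
                for i3 in range(2):
                    expected[i1, i2 * 2 + i3] = t[i1, i2, i3]
        np.testing.assert_array_equal(mode_unfold(t, 1), expected)
        # mode-2: rows i2, columns cyclic (i3, i1): index i3 * I1 + i1
        expected2 = np.empty((2, 4))
        for i2 in range(2):
            for i3 in range(2):
                for i1 in range(2):
                    expected2[i2, i3 * 2 + i1] = t[i1, i2, i3]
        np.testing.assert_array_equal(mode_unfold(t, 2), expected2)

    def test_zero_tensor_unfolds_to_zero(self):
        assert not mode_unfold(np.zeros((3, 4, 5)), 3).any()

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            mode_unfold(np.zeros((2, 2, 2)), 4)


class TestFitMPCA:
    def test_bases_orthonormal_and_spectra_sorted(self, rng):
        vol = Volume(rng.normal(0, 1, (12, 10, 8)))
        basis = fit_mpca(vol, K=5)
        basis.validate()  # orthonormality to 1e-10, nonincreasing spectra
        assert basis.n_iterations >= 1

    def test_rank_one_slices_captured_by_k1(self, rng):
        a = rng.normal(0, 1, 9)
        b = rng.normal(0, 1, 7)
        s = rng.normal(0, 3, 11)
        data = np.einsum("m,i,j->ijm", s, a, b)
        basis = fit_mpca(data, K=1)
        out = mpca_denoise(data, basis).data
        assert np.abs(out - data).max() < 1e-8
        # scatter by direct summation: sum_m ||(s_m - sbar) a b^T||_F^2
        direct = np.sum(
            (s - s.mean()) ** 2 * (a**2).sum() * (b**2).sum()
        )
        assert basis.scatter == pytest.approx(direct, rel=1e-10)
        assert basis.eigvals1[0] == pytest.approx(direct, rel=1e-10)
        assert basis.eigvals1[1:].max() < 1e-8 * direct

    def test_single_pass_matches_dense_eigen_oracle(self, rng):
        data = rng.normal(0, 1, (12, 10, 8))
        basis = fit_mpca(data, K=6, max_iter=1)
        slices = np.moveaxis(data, 2, 0)
        vals1, vecs1 = mode_scatter_eig(slices, 1)
        vals2, vecs2 = mode_scatter_eig(slices, 2)
        np.testing.assert_allclose(basis.eigvals1, vals1, atol=1e-8)
        np.testing.assert_allclose(basis.eigvals2, vals2, atol=1e-8)
        _match_up_to_sign(basis.U1, vecs1, 1e-8)
        _match_up_to_sign(basis.U2, vecs2, 1e-8)

    def test_fit_is_deterministic(self, rng):
        data = rng.normal(0, 1, (10, 9, 6))
        b1 = fit_mpca(data, K=4)
        b2 = fit_mpca(data, K=4)
        np.testing.assert_array_equal(b1.U1, b2.U1)
        np.testing.assert_array_equal(b1.U2, b2.U2)

    def test_degenerate_column_slices_equal_vector_pca(self, rng):
        """With I2 = 1 the slices are column vectors and mode-1 MPCA reduces
        to ordinary PCA on those vectors (scikit-learn as oracle)."""
        from sklearn.decomposition import PCA

        data = rng.normal(0, 2, (7, 1, 30))  # 30 samples of R^7
        basis = fit_mpca(data, K=1)
        vectors = np.moveaxis(data, 2, 0)[:, :, 0]
        pca = PCA(n_components=7).fit(vectors)
        _match_up_to_sign(basis.U1, pca.components_.T, 1e-8)
        np.testing.assert_allclose(
            basis.eigvals1,
            pca.explained_variance_ * (vectors.shape[0] - 1),
            atol=1e-8,
        )

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="slices"):
            fit_mpca(rng.normal(0, 1, (5, 5, 1)), K=2)
        with pytest.raises(ValueError, match="K"):
            fit_mpca(rng.normal(0, 1, (5, 4, 6)), K=6)
        with pytest.raises(ValueError, match="K"):
            fit_mpca(rng.normal(0, 1, (5, 4, 6)), K=0)


class TestMPCAProject:
    def test_identity_bases_identity_map(self, rng):
        data = rng.normal(0, 1, (6, 5, 4))
        basis = fit_mpca(data, K=2)
        eye_basis = basis
        eye_basis.U1 = np.eye(6)
        eye_basis.U2 = np.eye(5)
        x = rng.normal(0, 1, (6, 5))
        np.testing.assert_array_equal(mpca_project(x, eye_basis), x)

    def test_full_bases_preserve_frobenius_norm(self, rng):
        data = rng.normal(0, 1, (8, 7, 5))
        basis = fit_mpca(data, K=3)
        x = rng.normal(0, 1, (8, 7))
        y = mpca_project(x, basis)
        assert np.sum(y**2) == pytest.approx(np.sum(x**2), abs=1e-8)

    def test_zero_slice_maps_to_zero(self, rng):
        basis = fit_mpca(rng.normal(0, 1, (6, 5, 4)), K=2)
        assert not mpca_project(np.zeros((6, 5)), basis).any()

    def test_shape_mismatch_rejected(self, rng):
        basis = fit_mpca(rng.normal(0, 1, (6, 5, 4)), K=2)
        with pytest.raises(ValueError, match="shape"):
            mpca_project(np.zeros((5, 6)), basis)


class TestMPCADenoise:
    def test_per_mode_full_rank_reconstructs_input(self, rng):
        # K is clipped per mode, so K = max(I1, I2) keeps every component
        # of both modes and the reconstruction is the identity.
        data = rng.normal(0, 1, (9, 7, 6))
        basis = fit_mpca(data, K=9)
        out = mpca_denoise(data, basis).data
        assert np.abs(out - data).max() < 1e-8

    def test_reconstruction_error_nonincreasing_in_k(self, rng):
        data = rng.normal(0, 1, (10, 8, 12))
        basis = fit_mpca(data, K=8)
        errors = [
            np.sum((mpca_denoise(data, basis, K=k).data - data) ** 2)
            for k in range(1, 11)
        ]
        assert all(e1 >= e2 - 1e-9 for e1, e2 in zip(errors, errors[1:]))
        assert errors[-1] < 1e-12 * np.sum(data**2)

    def test_one_sided_error_equals_discarded_eigenvalue_tail(self, rng):
        """Parseval: projecting centred slice rows onto the top-K mode-1
        eigenvectors leaves exactly the discarded mode-1 eigenvalue tail."""
        data = rng.normal(0, 1, (12, 10, 8))
        slices = np.moveaxis(data, 2, 0)
        vals1, _ = mode_scatter_eig(slices, 1)
        basis = fit_mpca(data, K=5)
        Xc = slices - slices.mean(axis=0)
        for K in (1, 4, 7, 12):
            P1 = basis.U1[:, :K] @ basis.U1[:, :K].T
            err = np.sum((Xc - np.einsum("ij,mjk->mik", P1, Xc)) ** 2)
            assert err == pytest.approx(vals1[K:].sum(), abs=1e-8)

    def test_idempotent(self, rng):
        data = rng.normal(0, 1, (9, 9, 7))
        basis = fit_mpca(data, K=4)
        once = mpca_denoise(data, basis).data
        twice = mpca_denoise(once, basis).data
        np.testing.assert_allclose(twice, once, atol=1e-10)

    def test_recenter_reconstructs_constant_volume(self):
        data = np.full((8, 8, 8), 42.0)
        basis = fit_mpca(data, K=3)
        out = mpca_denoise(data, basis, recenter=True).data
        np.testing.assert_allclose(out, 42.0, atol=1e-10)

    def test_k_out_of_range_rejected(self, rng):
        data = rng.normal(0, 1, (6, 5, 4))
        basis = fit_mpca(data, K=2)
        with pytest.raises(ValueError, match="K"):
            mpca_denoise(data, basis, K=7)
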
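"""Multilinear PCA truncation — stage 2 of the pipeline.

A 3D volume is treated as the slice set ``{X_1, ..., X_M}`` of I1 x I2
matrices (M = I3 slices along the third axis).  Multilinear PCA seeks one
orthonormal basis per in-plane mode, ``U1`` (I1 x I1) and ``U2`` (I2 x I2),
maximising the total scatter of the projected slices

    Psi = sum_m || Y_m - Ybar ||_F^2,    Y_m = U1^T X_m U2.

With full square bases the problem decouples: each ``U^(n)`` is the
eigenbasis of the mode-n scatter matrix of the centred (and other-mode
projected) slices, ``sum_m C_m^(n) C_m^(n)T``, and the alternating
iteration converges after a single pass because an orthonormal projection
along the other mode leaves a mode's scatter matrix unchanged.  Denoising
keeps the leading K eigenvectors per mode and projects each slice's rows
and columns onto those subspaces::

    Xhat_m = U1[:, :K] U1[:, :K]^T  X_m  U2[:, :K] U2[:, :K]^T

discarding the trailing, noise-dominated components.  The slice axis
(mode 3) is never projected: slices are the samples.

By default the *raw* slice is projected, exactly as the truncated
reconstruction formula is usually printed.  When every slice is (nearly)
identical the centred scatter carries no information about the mean and
the raw projection is then arbitrary; the ``recenter`` option (project the
centred slice, add the mean back) is exact in that degenerate case and is
available everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume

__all__ = [
    "ProjectionBasis",
    "mode_unfold",
    "mode_fold",
    "fit_mpca",
    "mpca_project",
    "mpca_denoise",
]

# Cyclic column orders of the mode-n unfolding: rows index mode n, columns
# enumerate the remaining modes as (n+1, n+2) cyclically, the later mode
# varying fastest.
_UNFOLD_AXES = {1: (0, 1, 2), 2: (1, 2, 0), 3: (2, 0, 1)}


def mode_unfold(t: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n unfolding of a 3rd-order tensor.

    Row index = index along ``mode`` (1-based); columns enumerate the two
    remaining modes in cyclic order, e.g. mode 1 gives an I1 x (I2*I3)
    matrix with column index ``i2 * I3 + i3``.
    """
    t = np.asarray(t)
    if t.ndim != 3:
        raise ValueError(f"expected a 3rd-order tensor, got ndim={t.ndim}")
    if mode not in _UNFOLD_AXES:
        raise ValueError(f"mode must be 1, 2 or 3, got {mode}")
    axes = _UNFOLD_AXES[mode]
    return t.transpose(axes).reshape(t.shape[axes[0]], -1)


def mode_fold(m: np.ndarray, mode: int, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`mode_unfold` for the given tensor shape."""
    if mode not in _UNFOLD_AXES:
        raise ValueError(f"mode must be 1, 2 or 3, got {mode}")
    axes = _UNFOLD_AXES[mode]
    permuted_shape = tuple(shape[a] for a in axes)
    inverse = tuple(int(np.argsort(axes)[k]) for k in range(3))
    return np.asarray(m).reshape(permuted_shape).transpose(inverse)


@dataclass
class ProjectionBasis:
    """Fitted per-mode projection bases with spectra.

    ``U1``/``U2`` are full square orthonormal matrices whose columns are
    ordered by descending eigenvalue of the corresponding mode scatter
    matrix; ``K`` is the shared truncation rank; ``scatter`` is the total
    scatter Psi of the centred slices (the objective attained by any full
    orthonormal basis); ``mean_slice`` is the sample mean used for
    centring and for the ``recenter`` reconstruction.
    """

    U1: np.ndarray
    U2: np.ndarray
    eigvals1: np.ndarray
    eigvals2: np.ndarray
    K: int
    scatter: float
    n_iterations: int
    mean_slice: np.ndarray

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.U1.shape[0], self.U2.shape[0]

    @property
    def max_rank(self) -> int:
        """Largest admissible K: the bigger in-plane dimension (K is
        clipped per mode, so K = max(I1, I2) keeps every component of both
        modes and the reconstruction is exactly the identity)."""
        return max(self.slice_shape)

    def validate(self) -> None:
        for name, U in (("U1", self.U1), ("U2", self.U2)):
            err = np.max(np.abs(U.T @ U - np.eye(U.shape[0])))
            if err > 1e-10:
                raise ValueError(f"{name} is not orthonormal (max deviation {err:g})")
        for name, ev in (("eigvals1", self.eigvals1), ("eigvals2", self.eigvals2)):
            if np.any(np.diff(ev) > 1e-10 * max(abs(ev[0]), 1.0)):
                raise ValueError(f"{name} is not nonincreasing")
            if np.any(ev < -1e-10 * max(abs(ev[0]), 1.0)):
                raise ValueError(f"{name} has a significantly negative entry")
        if not 1 <= self.K <= max(self.slice_shape):
            raise ValueError(f"K={self.K} outside [1, {max(self.slice_shape)}]")


def _eig_descending(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a symmetric PSD matrix, descending order,
    each eigenvector's largest-magnitude entry made positive."""
    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    flip = vecs[np.argmax(np.abs(vecs), axis=0), np.arange(vecs.shape[1])] < 0
    vecs[:, flip] *= -1.0
    return vals, vecs


def _as_slices(vol: Volume | np.ndarray) -> np.ndarray:
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={data.ndim}")
    return np.moveaxis(data, 2, 0)  # (M, I1, I2)


def fit_mpca(
    vol: Volume | np.ndarray,
    K: int,
    max_iter: int = 5,
    tol: float = 1e-6,
) -> ProjectionBasis:
    """Fit the per-mode scatter eigenbases of a slice set.

    Alternates over the two in-plane modes: projects the centred slices
    along the other mode, accumulates that mode's scatter matrix and
    replaces its basis with the scatter eigenvectors, stopping when the
    scatter captured by the leading K components per mode changes by a
    relative factor below ``tol`` (or after ``max_iter`` passes; full
    square bases make the first pass already optimal, so the loop
    normally exits at pass 2).
    """
    X = _as_slices(vol)
    M, I1, I2 = X.shape
    if M < 2:
        raise ValueError("need at least 2 slices to define a scatter")
    if not 1 <= K <= max(I1, I2):
        raise ValueError(f"K={K} outside [1, max(I1, I2)={max(I1, I2)}]")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")

    mean_slice = X.mean(axis=0)
    Xc = X - mean_slice
    total_scatter = float(np.sum(Xc**2))

    U1 = np.eye(I1)
    U2 = np.eye(I2)
    ev1 = np.zeros(I1)
    ev2 = np.zeros(I2)
    captured_prev: float | None = None
    n_iterations = 0
    for _ in range(max_iter):
        n_iterations += 1
        C = Xc @ U2  # mode-2 projection: C_m = (X_m - Xbar) U2
        S1 = np.einsum("mij,mkj->ik", C, C)
        ev1, U1 = _eig_descending(S1)
        C = np.einsum("ji,mjk->mik", U1, Xc)  # mode-1 projection: U1^T (X_m - Xbar)
        S2 = np.einsum("mji,mjk->ik", C, C)
        ev2, U2 = _eig_descending(S2)
        captured = float(ev1[: min(K, I1)].sum() + ev2[: min(K, I2)].sum())
        if captured_prev is not None:
            if abs(captured - captured_prev) <= tol * max(captured_prev, 1e-300):
                break
        captured_prev = captured

    return ProjectionBasis(
        U1=U1,
        U2=U2,
        eigvals1=ev1,
        eigvals2=ev2,
        K=int(K),
        scatter=total_scatter,
        n_iterations=n_iterations,
        mean_slice=mean_slice,
    )


def mpca_project(slice_: np.ndarray, basis: ProjectionBasis) -> np.ndarray:
    """Principal-component slice ``Y = U1^T X U2`` (full bases: an isometry)."""
    slice_ = np.asarray(slice_, dtype=np.float64)
    if slice_.shape != basis.slice_shape:
        raise ValueError(
            f"slice shape {slice_.shape} does not match basis {basis.slice_shape}"
        )
    return basis.U1.T @ slice_ @ basis.U2


def mpca_denoise(
    vol: Volume | np.ndarray,
    basis: ProjectionBasis,
    K: int | None = None,
    recenter: bool = False,
) -> Volume:
    """Truncated multilinear reconstruction of every slice.

    Projects each slice's rows onto the span of the leading K columns of
    ``U1`` and its columns onto the leading K columns of ``U2`` (K is
    clipped per mode to that mode's dimension).  ``recenter`` applies the
    projection to the centred slice and adds the mean slice back.
    """
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol, dtype=np.float64)
    X = _as_slices(data)
    if X.shape[1:] != basis.slice_shape:
        raise ValueError(
            f"slice shape {X.shape[1:]} does not match basis {basis.slice_shape}"
        )
    K = basis.K if K is None else int(K)
    I1, I2 = basis.slice_shape
    if not 1 <= K <= max(I1, I2):
        raise ValueError(f"K={K} outside [1, max(I1, I2)={max(I1, I2)}]")
    K1, K2 = min(K, I1), min(K, I2)
    P1 = basis.U1[:, :K1] @ basis.U1[:, :K1].T
    P2 = basis.U2[:, :K2] @ basis.U2[:, :K2].T
    if recenter:
        Xhat = np.einsum("ij,mjk,kl->mil", P1, X - basis.mean_slice, P2)
        Xhat += basis.mean_slice
    else:
        Xhat = np.einsum("ij,mjk,kl->mil", P1, X, P2)
    out = np.moveaxis(Xhat, 0, 2)
    if isinstance(vol, Volume):
        return vol.with_data(out)
    return Volume(data=out)
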
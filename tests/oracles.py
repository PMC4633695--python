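"""Independent literal-loop reference implementations used only by tests.

These oracles implement the blockwise NLM weighted average and the MPCA
mode-scatter eigenproblem by direct, unoptimised loops so the package's
vectorised code paths can be checked against them.  They deliberately
share only the documented conventions (normalised patch distance, mirror
padding, clipped candidate centres, grid with appended last index), not
any code.
"""

from __future__ import annotations

import itertools

import numpy as np


def grid_axis(n: int, stride: int) -> list[int]:
    centers = list(range(0, n, stride))
    if centers[-1] != n - 1:
        centers.append(n - 1)
    return centers


def nlm3d_bruteforce(
    data: np.ndarray,
    search_radius: int,
    patch_radius: int,
    stride: int,
    h: float,
    self_weight_policy: str = "cap_at_max_neighbor",
) -> np.ndarray:
    """Literal blockwise NLM: loop over blocks, candidates and voxels."""
    data = np.asarray(data, dtype=np.float64)
    r, R = patch_radius, search_radius
    w = 2 * r + 1
    padded = np.pad(data, r, mode="reflect")

    def patch(c):
        return padded[tuple(slice(x, x + w) for x in c)]

    shape = data.shape
    grids = [grid_axis(n, stride) for n in shape]
    accum = np.zeros(shape)
    count = np.zeros(shape, dtype=int)
    h2 = h * h
    for i in itertools.product(*grids):
        ref = patch(i)
        weights = []
        cands = []
        self_pos = None
        for t in itertools.product(range(-R, R + 1), repeat=3):
            j = tuple(i[k] + t[k] for k in range(3))
            if any(not 0 <= j[k] < shape[k] for k in range(3)):
                continue
            if j == i:
                self_pos = len(weights)
                weights.append(None)  # fill later per policy
                cands.append(j)
                continue
            d = float(np.sum((ref - patch(j)) ** 2)) / ref.size
            weights.append(np.exp(-d / h2))
            cands.append(j)
        others = [x for x in weights if x is not None]
        if self_weight_policy == "as_formula" or not others:
            weights[self_pos] = 1.0
        else:
            weights[self_pos] = max(others)
        Z = sum(weights)
        if Z <= 0.0:
            weights = [0.0] * len(weights)
            weights[self_pos] = 1.0
            Z = 1.0
        block = np.zeros((w, w, w))
        for wt, j in zip(weights, cands):
            block += (wt / Z) * patch(j)
        for p in itertools.product(range(-r, r + 1), repeat=3):
            v = tuple(i[k] + p[k] for k in range(3))
            if any(not 0 <= v[k] < shape[k] for k in range(3)):
                continue
            accum[v] += block[tuple(p[k] + r for k in range(3))]
            count[v] += 1
    assert count.min() >= 1, "grid must cover every voxel"
    return accum / count


def mode_scatter_eig(slices: np.ndarray, mode: int):
    """Dense eigendecomposition of one mode's scatter of centred slices.

    ``slices`` has shape (M, I1, I2); mode 1 scatters rows, mode 2
    columns.  Returns (eigvals descending, eigvecs by column).
    """
    Xc = slices - slices.mean(axis=0)
    if mode == 1:
        S = sum(c @ c.T for c in Xc)
    elif mode == 2:
        S = sum(c.T @ c for c in Xc)
    else:
        raise ValueError(mode)
    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]
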
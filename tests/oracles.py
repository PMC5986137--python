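"""Independent oracles used to validate the analytic implementations.

These deliberately avoid the singular-value identities used by the package:
the Procrustes fit oracle minimizes the residual by searching over explicit
rotation (and reflection) matrices with a closed-form scale, and the
correlation oracle is a direct moment computation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def _center_normalize(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim == 1:
        mat = mat[:, None]
    centered = mat - mat.mean(axis=0)
    return centered / np.sqrt((centered**2).sum())


def _pad(mat: np.ndarray, width: int) -> np.ndarray:
    if mat.shape[1] == width:
        return mat
    out = np.zeros((mat.shape[0], width))
    out[:, : mat.shape[1]] = mat
    return out


def brute_force_procrustes_fit(parent, sub, grid_2d: float = 1e-5) -> float:
    """Procrustes fit by explicit search over orthogonal transforms.

    Both matrices are centered, scaled to unit sum of squares, and padded with
    zero columns to a common width q <= 3.  For the optimal orthogonal map R
    and scale c, the residual is ``1 - max_R tr(X^T Y R)^2`` (the scale is
    closed-form once R is fixed); the maximization is done by a dense grid
    over rotation angles — one angle in 2-D at ``grid_2d`` resolution, Euler
    angles in 3-D with a local refinement — with reflections included.
    """
    x = _center_normalize(parent)
    y = _center_normalize(sub)
    q = max(x.shape[1], y.shape[1])
    if q > 3:
        raise ValueError("oracle supports widths up to 3")
    x, y = _pad(x, q), _pad(y, q)
    m = x.T @ y  # trace(X^T Y R) = sum(M * R.T)

    if q == 1:
        best = abs(m[0, 0])
    elif q == 2:
        theta = np.arange(0.0, 2.0 * np.pi, grid_2d)
        cos, sin = np.cos(theta), np.sin(theta)
        # R(theta) proper; F @ R(theta) covers reflections (F = diag(1,-1))
        tr_rot = (m[0, 0] + m[1, 1]) * cos + (m[1, 0] - m[0, 1]) * sin
        tr_ref = (m[0, 0] - m[1, 1]) * cos + (m[1, 0] + m[0, 1]) * sin
        best = max(np.abs(tr_rot).max(), np.abs(tr_ref).max())
    else:
        best = 0.0
        flip = np.diag([1.0, 1.0, -1.0])
        coarse = np.linspace(0.0, 2.0 * np.pi, 25, endpoint=False)
        coarse_b = np.linspace(0.0, np.pi, 13)
        grid = np.array(np.meshgrid(coarse, coarse_b, coarse)).reshape(3, -1).T
        rots = Rotation.from_euler("zyz", grid).as_matrix()
        for reflect in (False, True):
            mats = rots @ flip if reflect else rots
            traces = np.abs(np.einsum("ij,kji->k", m, mats))
            start = grid[int(np.argmax(traces))]

            def neg_trace(angles, reflect=reflect):
                r = Rotation.from_euler("zyz", angles).as_matrix()
                if reflect:
                    r = r @ flip
                return -abs(np.trace(m @ r))

            res = minimize(neg_trace, start, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12,
                                    "maxiter": 4000})
            best = max(best, -res.fun)
    return float(best**2)


def squared_pearson(a, b) -> float:
    """Squared Pearson correlation computed from raw moments."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    da, db = a - a.mean(), b - b.mean()
    return float((da @ db) ** 2 / ((da @ da) * (db @ db)))


def rotation_matrix_2d(theta: float) -> np.ndarray:
    return np.array([[np.cos(theta), -np.sin(theta)],
                     [np.sin(theta), np.cos(theta)]])
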
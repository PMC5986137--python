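"""Congruence statistics between specimen constellations in shape space.

The core statistic compares two ordinations of the same specimens — e.g. the
tangent-space shape variables of a full landmark dataset and of a landmark
subset — by symmetric ordinary Procrustes superimposition of the specimen
constellations themselves (the PROTEST fit statistic).  Both matrices are
column-centered and scaled to unit total sum of squares; the residual after
the optimal rotation/reflection and scaling is the Procrustes sum of squares
(PSS), and congruence is reported as ``fit = 1 - PSS``.

With X and Y so normalized, the minimized residual is ``1 - (sum sigma_i)^2``
where ``sigma_i`` are the singular values of ``X.T @ Y``.  Matching the
statistical dimensions of the two matrices by padding the narrower one with
zero columns leaves the singular values — hence PSS — unchanged, so the
computation is done on the original widths.

``two_block_pls_correlation`` implements the first-axis correlation from
two-block partial least squares.  It is provided as a contrast only: because
a landmark subset is literally a subset of the parent variables, PLS finds
highly correlated linear combinations even at severe subsampling, making it
an inflated congruence measure.
"""

from __future__ import annotations

import numpy as np

from .containers import ProcrustesFit
from .exceptions import DegenerateDataError, SpecimenMismatchError

__all__ = [
    "ordination_procrustes_fit",
    "size_fit",
    "two_block_pls_correlation",
]

# Relative variance below which a constellation is treated as degenerate.
_VAR_EPS = 1e-30


def _center_normalize(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim == 1:
        mat = mat[:, None]
    centered = mat - mat.mean(axis=0)
    total_ss = float((centered**2).sum())
    if total_ss <= _VAR_EPS:
        raise DegenerateDataError(
            f"{name} constellation has zero variance; congruence is undefined"
        )
    return centered / np.sqrt(total_ss)


def _check_rows(parent_vars, sub_vars) -> None:
    n1 = np.shape(parent_vars)[0]
    n2 = np.shape(sub_vars)[0]
    if n1 != n2:
        raise SpecimenMismatchError(
            f"specimen counts differ: {n1} vs {n2}; both datasets must "
            "describe the same specimens in the same order"
        )
    if n1 < 3:
        raise SpecimenMismatchError("at least 3 specimens are required")


def ordination_procrustes_fit(parent_vars, sub_vars) -> ProcrustesFit:
    """Symmetric Procrustes fit between two specimen constellations.

    Parameters
    ----------
    parent_vars, sub_vars
        Matrices of shape (n, q) and (n, q') whose rows are the same n
        specimens in two (possibly different-dimensional) variable spaces.
        1-D inputs are treated as single columns.

    Returns
    -------
    ProcrustesFit
        ``fit = (sum of singular values of X~.T Y~)**2`` and ``pss = 1 - fit``
        for the centered, unit-sum-of-squares matrices X~, Y~.  The statistic
        is symmetric in its arguments and invariant to orthogonal
        transformation (including reflection), uniform scaling, and
        column-wise constant shifts of either argument.
    """
    _check_rows(parent_vars, sub_vars)
    x = _center_normalize(parent_vars, "parent")
    y = _center_normalize(sub_vars, "subsample")
    sigma = np.linalg.svd(x.T @ y, compute_uv=False)
    fit = float(sigma.sum() ** 2)
    return ProcrustesFit(pss=1.0 - fit, fit=fit)


def size_fit(parent_sizes, sub_sizes) -> ProcrustesFit:
    """Procrustes fit between two centroid-size vectors.

    This is the one-column specialization of
    :func:`ordination_procrustes_fit`; analytically the fit equals the squared
    Pearson correlation of the two vectors (reflection is permitted, so the
    sign of the correlation is irrelevant).
    """
    parent = np.asarray(parent_sizes, dtype=float).ravel()
    sub = np.asarray(sub_sizes, dtype=float).ravel()
    return ordination_procrustes_fit(parent[:, None], sub[:, None])


def two_block_pls_correlation(parent_vars, sub_vars) -> float:
    """Correlation of the first pair of two-block PLS axes.

    The between-block covariance matrix of the column-centered matrices is
    decomposed by SVD; the returned value is the absolute Pearson correlation
    between the specimen scores on the first left and right singular vectors.
    Demonstration-only congruence measure (see module docstring).
    """
    _check_rows(parent_vars, sub_vars)
    x = _center_normalize(parent_vars, "parent")
    y = _center_normalize(sub_vars, "subsample")
    u, _, vt = np.linalg.svd(x.T @ y)
    a = x @ u[:, 0]
    b = y @ vt[0, :]
    denom = np.linalg.norm(a - a.mean()) * np.linalg.norm(b - b.mean())
    if denom <= 0:
        raise DegenerateDataError("degenerate PLS scores")
    r = float((a - a.mean()) @ (b - b.mean()) / denom)
    return abs(r)
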
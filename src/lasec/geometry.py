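"""Generalized Procrustes alignment (GPA) and tangent-space projection.

GPA removes the non-shape components of landmark variation — position,
orientation, and scale — by iteratively centering each configuration,
scaling it to unit centroid size, and rotating it onto the current mean
shape (the SVD solution of the orthogonal Procrustes problem).  The aligned
configurations are then projected from the curved pre-shape sphere onto the
linear tangent space at the mean, where ordinary Euclidean statistics apply.

The class :class:`GeneralizedProcrustesAlignment` exposes the procedure as a
scikit-learn transformer; :func:`gpa` is the functional entry point.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import AlignedShapeData, LandmarkConfigurationSet
from .exceptions import DegenerateSpecimenError, DimensionalityError

__all__ = [
    "centroid_size",
    "centroid_sizes",
    "tangent_project",
    "gpa",
    "GeneralizedProcrustesAlignment",
]


def centroid_size(config: np.ndarray) -> float:
    """Centroid size of one configuration: sqrt of the summed squared
    distances of all landmarks from their centroid.

    Returns 0.0 for a fully coincident configuration; such configurations are
    rejected downstream by GPA.
    """
    config = np.asarray(config, dtype=float)
    centered = config - config.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def centroid_sizes(coords: np.ndarray) -> np.ndarray:
    """Centroid size of every configuration in an (n, p, d) stack."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=1, keepdims=True)
    return np.sqrt((centered**2).sum(axis=(1, 2)))


def tangent_project(aligned: np.ndarray, mean_vec: np.ndarray) -> np.ndarray:
    """Project flattened aligned configurations onto the tangent space.

    The tangent space at the mean shape is the hyperplane through the mean
    orthogonal to the mean direction.  With ``mean_vec`` of unit norm, each
    row is mapped to ``row - (row . mean_vec - 1) * mean_vec``, so the
    residual ``row' - mean_vec`` is orthogonal to ``mean_vec``.
    """
    aligned = np.atleast_2d(np.asarray(aligned, dtype=float))
    mean_vec = np.asarray(mean_vec, dtype=float).ravel()
    norm = np.linalg.norm(mean_vec)
    if norm < 1e-12:
        raise ValueError("mean vector must be nonzero for tangent projection")
    mean_vec = mean_vec / norm
    coef = aligned @ mean_vec - 1.0
    return aligned - coef[:, None] * mean_vec


def _optimal_rotation(config: np.ndarray, target: np.ndarray,
                      allow_reflection: bool) -> np.ndarray:
    """Orthogonal (optionally rotation-only) Procrustes solution mapping
    ``config`` onto ``target``; both (p, d) and centered."""
    u, _, vt = np.linalg.svd(config.T @ target)
    rot = u @ vt
    if not allow_reflection and np.linalg.det(rot) < 0:
        u[:, -1] *= -1.0
        rot = u @ vt
    return rot


def gpa(
    data: LandmarkConfigurationSet | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
    allow_reflection: bool = True,
) -> AlignedShapeData:
    """Generalized Procrustes alignment with tangent projection.

    Parameters
    ----------
    data
        A :class:`LandmarkConfigurationSet` or a raw (n, p, d) array of
        complete, unaligned configurations (n >= 2, p >= 3).
    tol
        Convergence tolerance on the change in the total squared distance of
        the aligned configurations to the mean shape.
    max_iter
        Iteration cap; on hitting it the result is returned with
        ``gpa_converged=False`` and a warning.
    allow_reflection
        Whether the per-specimen orthogonal alignment may include a
        reflection.  The default matches the reflection-permissive symmetric
        Procrustes convention used by the congruence statistic; set False for
        rigid-only alignment.

    Returns
    -------
    AlignedShapeData
        Tangent-space shape variables, raw centroid sizes, the unit-size mean
        shape, and convergence diagnostics.
    """
    if isinstance(data, LandmarkConfigurationSet):
        coords = data.coords
        specimen_ids = data.specimen_ids
    else:
        coords = np.asarray(data, dtype=float)
        specimen_ids = tuple(f"specimen_{i}" for i in range(coords.shape[0]))
    if coords.ndim != 3:
        raise DimensionalityError("expected an (n, p, d) coordinate array")
    n, p, d = coords.shape
    if n < 2:
        raise DimensionalityError("GPA needs at least 2 specimens")
    if p < 3:
        raise DimensionalityError("GPA needs at least 3 landmarks")

    centered = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centered**2).sum(axis=(1, 2)))
    if np.any(sizes <= 0):
        bad = int(np.argmin(sizes))
        raise DegenerateSpecimenError(
            f"specimen {specimen_ids[bad]!r} has zero centroid size "
            "(all landmarks coincide); cannot be aligned"
        )
    scaled = centered / sizes[:, None, None]

    # The mean that minimizes the total squared distance given the current
    # rotations is the arithmetic mean of the aligned configurations; the
    # recorded objective is measured against it, which makes the sequence of
    # objective values provably non-increasing.  Rotation targets are
    # scale-invariant, so rescaling the mean would not change them.
    # Initialize by superimposing every configuration onto the first
    # specimen.  This makes the starting point — hence the fixed point
    # reached — independent of the input orientations: any per-specimen
    # transform is absorbed here, and the first specimen's own orientation
    # only rotates the whole set, which the final canonicalization removes.
    aligned = scaled.copy()
    u0, _, vt0 = np.linalg.svd(aligned.transpose(0, 2, 1) @ aligned[0])
    if not allow_reflection:
        det0 = np.linalg.det(u0 @ vt0)
        u0[det0 < 0, :, -1] *= -1.0
    aligned = aligned @ (u0 @ vt0)
    mean = aligned.mean(axis=0)
    ss_history: list[float] = []
    prev_ss = np.inf
    last_change = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        # batched orthogonal Procrustes: one (d x d) SVD per specimen
        u, _, vt = np.linalg.svd(aligned.transpose(0, 2, 1) @ mean)
        if not allow_reflection:
            det = np.linalg.det(u @ vt)
            u[det < 0, :, -1] *= -1.0
        aligned = aligned @ (u @ vt)
        mean = aligned.mean(axis=0)
        ss = float(((aligned - mean) ** 2).sum())
        ss_history.append(ss)
        last_change = prev_ss - ss
        if last_change < tol:
            converged = True
            break
        prev_ss = ss
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations "
            f"(last change {last_change:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )

    # Canonical orientation: the aligned set is unique only up to a common
    # orthogonal transform, so rotate everything onto the principal axes of
    # the mean shape with a deterministic sign convention.  This makes the
    # output invariant to per-specimen similarity transforms of the input.
    _, _, vt_m = np.linalg.svd(mean, full_matrices=False)
    canon = vt_m.T
    m_rot = mean @ canon
    signs = np.sign(m_rot[np.argmax(np.abs(m_rot), axis=0), np.arange(d)])
    signs[signs == 0] = 1.0
    canon = canon * signs
    if not allow_reflection and np.linalg.det(canon) < 0:
        canon[:, -1] *= -1.0  # keep the transform proper in rigid-only mode
    mean = mean @ canon
    aligned = aligned @ canon

    mean_size = np.linalg.norm(mean)
    if mean_size < 1e-12:
        raise DegenerateSpecimenError(
            "mean shape collapsed to zero centroid size during alignment"
        )
    mean_unit = mean / mean_size
    flat = aligned.reshape(n, p * d)
    shape_vars = tangent_project(flat, mean_unit.ravel())
    return AlignedShapeData(
        shape_vars=shape_vars,
        centroid_sizes=sizes,
        mean_shape=mean_unit,
        gpa_iterations=iterations,
        gpa_converged=converged,
        ss_history=tuple(ss_history),
    )


def _as_configs(X, n_dims: int | None) -> np.ndarray:
    """Coerce input to an (n, p, d) stack, unflattening 2-D input."""
    if isinstance(X, LandmarkConfigurationSet):
        return X.coords
    X = np.asarray(X, dtype=float)
    if X.ndim == 3:
        return X
    if X.ndim == 2:
        if n_dims is None:
            raise DimensionalityError(
                "flat-matrix input requires n_dims to unflatten columns"
            )
        if X.shape[1] % n_dims:
            raise DimensionalityError(
                f"{X.shape[1]} columns not divisible by n_dims={n_dims}"
            )
        return X.reshape(X.shape[0], X.shape[1] // n_dims, n_dims)
    raise DimensionalityError(f"cannot interpret array of ndim {X.ndim}")


class GeneralizedProcrustesAlignment(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer wrapping generalized Procrustes alignment.

    ``fit`` runs GPA on a training set of configurations and stores the
    consensus (mean) shape.  ``transform`` superimposes configurations onto
    that consensus by ordinary Procrustes alignment (center, scale to unit
    centroid size, rotate) followed by tangent projection, returning flat
    shape variables.  ``fit_transform`` returns the jointly aligned training
    shape variables, which is the standard way to extract shape data.

    Parameters
    ----------
    tol, max_iter, allow_reflection
        Passed through to :func:`gpa`.
    n_dims : int, optional
        Physical dimensionality, required only when inputs are flat
        (n, p*d) matrices rather than (n, p, d) arrays or
        :class:`LandmarkConfigurationSet`.

    Attributes
    ----------
    mean_shape_ : (p, d) array with unit centroid size.
    shape_vars_ : tangent-space shape variables of the training data.
    centroid_sizes_ : raw centroid sizes of the training specimens.
    n_iter_ : GPA iterations used.
    converged_ : whether GPA converged within ``max_iter``.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100,
                 allow_reflection: bool = True, n_dims: int | None = None):
        self.tol = tol
        self.max_iter = max_iter
        self.allow_reflection = allow_reflection
        self.n_dims = n_dims

    def fit(self, X, y=None):
        configs = _as_configs(X, self.n_dims)
        result = gpa(configs, tol=self.tol, max_iter=self.max_iter,
                     allow_reflection=self.allow_reflection)
        self.mean_shape_ = result.mean_shape
        self.shape_vars_ = result.shape_vars
        self.centroid_sizes_ = result.centroid_sizes
        self.n_iter_ = result.gpa_iterations
        self.converged_ = result.gpa_converged
        self.result_ = result
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "mean_shape_"):
            raise RuntimeError("GeneralizedProcrustesAlignment is not fitted")
        configs = _as_configs(X, self.n_dims)
        n, p, d = configs.shape
        if (p, d) != self.mean_shape_.shape:
            raise DimensionalityError(
                f"expected configurations of shape {self.mean_shape_.shape}, "
                f"got {(p, d)}"
            )
        centered = configs - configs.mean(axis=1, keepdims=True)
        sizes = np.sqrt((centered**2).sum(axis=(1, 2)))
        if np.any(sizes <= 0):
            raise DegenerateSpecimenError("zero-centroid-size configuration")
        scaled = centered / sizes[:, None, None]
        out = np.empty_like(scaled)
        for i in range(n):
            rot = _optimal_rotation(scaled[i], self.mean_shape_,
                                    self.allow_reflection)
            out[i] = scaled[i] @ rot
        return tangent_project(out.reshape(n, p * d),
                               self.mean_shape_.ravel())

    def fit_transform(self, X, y=None):
        return self.fit(X).shape_vars_
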
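"""In-memory containers for landmark coordinate data and analysis results.

The central object is :class:`LandmarkConfigurationSet`, a validated bundle of
``n_specimens x n_landmarks x n_dims`` Cartesian coordinates with specimen and
landmark labels.  Downstream results (Procrustes-aligned shape variables,
pairwise fit statistics, sampling curves) are plain frozen dataclasses so they
can be inspected, serialized, and compared without hidden state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    CompletenessError,
    DimensionalityError,
    LandmarkDataError,
)

__all__ = [
    "LandmarkConfigurationSet",
    "AlignedShapeData",
    "ProcrustesFit",
    "SamplingSpec",
    "SamplingCurves",
    "SimulationSpec",
]

#: Thresholds reported in sampling-curve summaries by default.
DEFAULT_THRESHOLDS = (0.90, 0.95, 0.99)


@dataclass(frozen=True)
class LandmarkConfigurationSet:
    """A complete set of landmark configurations, one per specimen.

    Parameters
    ----------
    coords
        Real array of shape ``(n_specimens, n_landmarks, n_dims)``.  All axes
        must share the same physical units.  The data are assumed raw:
        unaligned, unscaled, and complete (no missing values).
    specimen_ids, landmark_ids
        Optional labels; generated automatically when omitted.
    """

    coords: np.ndarray
    specimen_ids: tuple[str, ...] = ()
    landmark_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3:
            raise DimensionalityError(
                f"coords must be a 3-axis array (specimens x landmarks x dims); "
                f"got shape {coords.shape}"
            )
        n, p, d = coords.shape
        if d not in (2, 3):
            raise DimensionalityError(f"n_dims must be 2 or 3, got {d}")
        if p < 3:
            raise DimensionalityError(
                f"at least 3 landmarks are required to define shape, got {p}"
            )
        if not np.isfinite(coords).all():
            bad = np.argwhere(~np.isfinite(coords))[0]
            raise CompletenessError(
                "coordinate data must be complete; non-finite value at "
                f"specimen {bad[0]}, landmark {bad[1]}, axis {bad[2]}"
            )
        object.__setattr__(self, "coords", coords)
        spec_ids = tuple(self.specimen_ids) or tuple(
            f"specimen_{i}" for i in range(n)
        )
        lm_ids = tuple(self.landmark_ids) or tuple(f"lm_{j}" for j in range(p))
        if len(spec_ids) != n:
            raise LandmarkDataError(
                f"{len(spec_ids)} specimen_ids for {n} specimens"
            )
        if len(lm_ids) != p:
            raise LandmarkDataError(f"{len(lm_ids)} landmark_ids for {p} landmarks")
        object.__setattr__(self, "specimen_ids", spec_ids)
        object.__setattr__(self, "landmark_ids", lm_ids)

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[2]

    def subset(self, landmark_indices) -> "LandmarkConfigurationSet":
        """Return a new set restricted to the given landmarks (order kept)."""
        idx = np.asarray(landmark_indices, dtype=int)
        if idx.ndim != 1 or len(idx) < 3:
            raise DimensionalityError(
                "a landmark subset needs at least 3 indices"
            )
        if len(np.unique(idx)) != len(idx):
            raise LandmarkDataError("duplicate landmark indices in subset")
        if idx.min() < 0 or idx.max() >= self.n_landmarks:
            raise LandmarkDataError(
                f"landmark indices out of range 0..{self.n_landmarks - 1}"
            )
        return LandmarkConfigurationSet(
            coords=self.coords[:, idx, :],
            specimen_ids=self.specimen_ids,
            landmark_ids=tuple(self.landmark_ids[i] for i in idx),
        )


@dataclass(frozen=True)
class AlignedShapeData:
    """Output of generalized Procrustes alignment.

    ``shape_vars`` are tangent-space shape coordinates flattened to one row per
    specimen (landmark-major: x1, y1[, z1], x2, ...).  ``centroid_sizes`` are
    measured on the raw configurations, before any scaling, and retain the
    original units.  ``mean_shape`` has unit centroid size.
    """

    shape_vars: np.ndarray
    centroid_sizes: np.ndarray
    mean_shape: np.ndarray
    gpa_iterations: int
    gpa_converged: bool
    #: Total squared distance to the mean shape after each rotation sweep.
    ss_history: tuple[float, ...] = ()

    @property
    def n_specimens(self) -> int:
        return self.shape_vars.shape[0]


@dataclass(frozen=True)
class ProcrustesFit:
    """Symmetric Procrustes congruence between two specimen constellations.

    ``pss`` is the residual sum of squares after symmetric ordinary Procrustes
    superimposition of the two normalized constellations; ``fit = 1 - pss``,
    so 1 means perfect congruence and values near 0 mean none.
    """

    pss: float
    fit: float

    def __post_init__(self) -> None:
        if abs((self.pss + self.fit) - 1.0) > 1e-12:
            raise ValueError("pss and fit must sum to 1")


@dataclass(frozen=True)
class SamplingSpec:
    """Resampling settings for a sampling-curve analysis."""

    n_iterations: int = 1000
    seed: int | None = None
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise LandmarkDataError("n_iterations must be >= 1")
        th = tuple(float(t) for t in self.thresholds)
        if any(not (0.0 < t < 1.0) for t in th):
            raise LandmarkDataError("thresholds must lie strictly in (0, 1)")
        if any(b <= a for a, b in zip(th, th[1:])):
            raise LandmarkDataError("thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds", th)


@dataclass(frozen=True)
class SamplingCurves:
    """Per-iteration fit trajectories plus median curves and threshold summary.

    ``landmark_counts`` runs from 3 to the full landmark count p.  The fit
    matrices have one row per subsampling iteration and one column per
    landmark count; ``landmark_orders`` stores the landmark permutation used
    by each iteration, so every fit value can be recomputed from it.
    ``threshold_table`` maps each threshold to the minimal landmark count at
    which the median curve reaches it, separately for the shape and size
    channels (``None`` when never reached).
    """

    landmark_counts: np.ndarray
    shape_fits: np.ndarray
    size_fits: np.ndarray
    shape_median: np.ndarray
    size_median: np.ndarray
    threshold_table: dict[float, dict[str, int | None]]
    landmark_orders: np.ndarray
    spec: SamplingSpec = field(default_factory=SamplingSpec)

    @property
    def n_iterations(self) -> int:
        return self.shape_fits.shape[0]

    @property
    def n_landmarks(self) -> int:
        return int(self.landmark_counts[-1])


@dataclass(frozen=True)
class SimulationSpec:
    """Settings for the multivariate-normal coordinate simulator.

    Coordinate variables share a compound-symmetric covariance matrix: a
    common ``variance`` on the diagonal and a single pairwise ``covariance``
    between every pair of the ``n_landmarks * n_dims`` variables.  Positive
    definiteness requires ``covariance / variance`` in
    ``(-1 / (p*d - 1), 1)``.
    """

    n_specimens: int
    n_landmarks: int
    n_dims: int = 2
    covariance: float = 0.1
    variance: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_specimens < 1:
            raise LandmarkDataError("n_specimens must be >= 1")
        if self.n_landmarks < 3:
            raise DimensionalityError("n_landmarks must be >= 3")
        if self.n_dims not in (2, 3):
            raise DimensionalityError("n_dims must be 2 or 3")
        if self.variance <= 0:
            raise LandmarkDataError("variance must be positive")
        q = self.n_landmarks * self.n_dims
        rho = self.covariance / self.variance
        if not (-1.0 / (q - 1) < rho < 1.0):
            raise LandmarkDataError(
                "implied covariance matrix is not positive definite: need "
                f"covariance/variance in (-1/{q - 1}, 1), got {rho:.4g}"
            )
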
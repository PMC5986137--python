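"""The landmark sampling evaluation curve (LaSEC) procedure.

Given a complete landmark dataset, the procedure asks how well random subsets
of landmarks reproduce the *pattern* of shape (and size) variation among the
specimens.  One iteration draws a uniform random permutation of the p
landmarks, then for every prefix of length k = 3 ... p realigns the
k-landmark dataset by generalized Procrustes alignment and measures the
symmetric Procrustes fit (1 - PSS) between the subsampled and the parent
specimen constellations in full shape space, and likewise for centroid size.
Repeating for many iterations yields a band of fit trajectories; the median
trajectory and the smallest landmark counts reaching fixed fit thresholds
(0.90, 0.95, 0.99 by default) summarize how many landmarks are enough.

Starting every iteration from a single stored permutation and taking prefixes
is equivalent to "draw 3 random landmarks, then add one at random" and makes
each iteration exactly reproducible from its stored landmark order.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .congruence import ordination_procrustes_fit, size_fit
from .containers import (
    DEFAULT_THRESHOLDS,
    AlignedShapeData,
    LandmarkConfigurationSet,
    ProcrustesFit,
    SamplingCurves,
    SamplingSpec,
)
from .exceptions import (
    DegenerateDataError,
    DegenerateSpecimenError,
    DimensionalityError,
    LandmarkDataError,
)
from .geometry import _as_configs, gpa

__all__ = [
    "lasec",
    "landmarks_at_threshold",
    "informed_subsample_fit",
    "LandmarkSamplingCurve",
]


def _as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _channel_fits(
    parent: AlignedShapeData,
    sub_coords: np.ndarray,
    tol: float,
    max_iter: int,
    allow_reflection: bool,
) -> tuple[float, float]:
    """Shape and size fit of one landmark subset against the parent, with the
    documented degenerate fallback: a subset whose aligned constellation (or
    size vector) carries no variance scores fit 0 with a warning instead of
    aborting the iteration."""
    try:
        sub = gpa(sub_coords, tol=tol, max_iter=max_iter,
                  allow_reflection=allow_reflection)
    except DegenerateSpecimenError as exc:
        warnings.warn(
            f"degenerate landmark subset ({exc}); recording fit 0",
            RuntimeWarning, stacklevel=3,
        )
        return 0.0, 0.0
    try:
        shape = ordination_procrustes_fit(parent.shape_vars, sub.shape_vars).fit
    except DegenerateDataError as exc:
        warnings.warn(f"degenerate shape constellation ({exc}); fit 0",
                      RuntimeWarning, stacklevel=3)
        shape = 0.0
    try:
        size = size_fit(parent.centroid_sizes, sub.centroid_sizes).fit
    except DegenerateDataError as exc:
        warnings.warn(f"degenerate size vector ({exc}); fit 0",
                      RuntimeWarning, stacklevel=3)
        size = 0.0
    return shape, size


def _threshold_table(
    landmark_counts: np.ndarray,
    shape_median: np.ndarray,
    size_median: np.ndarray,
    thresholds,
) -> dict[float, dict[str, int | None]]:
    table: dict[float, dict[str, int | None]] = {}
    for t in thresholds:
        entry: dict[str, int | None] = {}
        for channel, median in (("shape", shape_median), ("size", size_median)):
            hits = np.nonzero(median >= t)[0]
            entry[channel] = int(landmark_counts[hits[0]]) if hits.size else None
        table[float(t)] = entry
    return table


def lasec(
    data,
    spec: SamplingSpec | None = None,
    *,
    n_dims: int | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
    allow_reflection: bool = True,
    show_progress: bool = False,
) -> SamplingCurves:
    """Run the full sampling-curve analysis on a complete landmark dataset.

    Parameters
    ----------
    data
        :class:`LandmarkConfigurationSet`, an (n, p, d) array, or a flat
        (n, p*d) matrix together with ``n_dims``.
    spec
        Resampling settings (iterations, seed, thresholds); defaults to 1000
        iterations with thresholds 0.90/0.95/0.99.
    show_progress
        Print a one-line progress count of completed iterations.

    Returns
    -------
    SamplingCurves

    Notes
    -----
    At k = p the subsample is the parent dataset itself up to a permutation of
    landmarks — a column permutation of the flat shape variables, under which
    the fit statistic is invariant — so the final fit is recorded as exactly 1
    for both channels without recomputation.
    """
    spec = spec or SamplingSpec()
    coords = _as_configs(data, n_dims)
    n, p, d = coords.shape
    if n < 3:
        raise LandmarkDataError("the analysis requires at least 3 specimens")
    if p < 3:
        raise DimensionalityError("the analysis requires at least 3 landmarks")
    data_set = (data if isinstance(data, LandmarkConfigurationSet)
                else LandmarkConfigurationSet(coords))

    parent = gpa(data_set, tol=tol, max_iter=max_iter,
                 allow_reflection=allow_reflection)

    landmark_counts = np.arange(3, p + 1)
    n_steps = p - 2
    shape_fits = np.empty((spec.n_iterations, n_steps))
    size_fits = np.empty((spec.n_iterations, n_steps))
    landmark_orders = np.empty((spec.n_iterations, p), dtype=int)

    children = _as_seed_sequence(spec.seed).spawn(spec.n_iterations)
    for it, child in enumerate(children):
        rng = np.random.default_rng(child)
        perm = rng.permutation(p)
        landmark_orders[it] = perm
        for j, k in enumerate(landmark_counts):
            if k == p:
                shape_fits[it, j] = 1.0
                size_fits[it, j] = 1.0
                continue
            sub_coords = coords[:, perm[:k], :]
            shape_fits[it, j], size_fits[it, j] = _channel_fits(
                parent, sub_coords, tol, max_iter, allow_reflection
            )
        if show_progress:
            print(f"\riteration {it + 1}/{spec.n_iterations}",
                  end="" if it + 1 < spec.n_iterations else "\n", flush=True)

    shape_median = np.median(shape_fits, axis=0)
    size_median = np.median(size_fits, axis=0)
    return SamplingCurves(
        landmark_counts=landmark_counts,
        shape_fits=shape_fits,
        size_fits=size_fits,
        shape_median=shape_median,
        size_median=size_median,
        threshold_table=_threshold_table(
            landmark_counts, shape_median, size_median, spec.thresholds
        ),
        landmark_orders=landmark_orders,
        spec=spec,
    )


def landmarks_at_threshold(
    curves: SamplingCurves, threshold: float, channel: str = "shape"
) -> int | None:
    """Smallest landmark count whose median fit reaches ``threshold``.

    Returns ``None`` when the median curve never reaches it (cannot happen
    for thresholds <= 1 evaluated on the full curve, whose last value is 1,
    but a truncated curve may fall short).
    """
    if not (0.0 < threshold < 1.0):
        raise LandmarkDataError("threshold must lie strictly in (0, 1)")
    if channel == "shape":
        median = curves.shape_median
    elif channel == "size":
        median = curves.size_median
    else:
        raise LandmarkDataError(f"unknown channel {channel!r}")
    hits = np.nonzero(median >= threshold)[0]
    return int(curves.landmark_counts[hits[0]]) if hits.size else None


def informed_subsample_fit(
    data,
    keep,
    *,
    n_dims: int | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
    allow_reflection: bool = True,
) -> tuple[ProcrustesFit, ProcrustesFit]:
    """Fit of a user-chosen landmark subset against the parent dataset.

    One single-shot step of the sampling procedure for an *informed* subset —
    e.g. one side of a bilaterally symmetric structure — which is expected to
    outperform the median of random subsets of the same size.  Returns the
    (shape, size) fit pair.
    """
    coords = _as_configs(data, n_dims)
    data_set = (data if isinstance(data, LandmarkConfigurationSet)
                else LandmarkConfigurationSet(coords))
    sub_set = data_set.subset(keep)  # validates indices
    parent = gpa(data_set, tol=tol, max_iter=max_iter,
                 allow_reflection=allow_reflection)
    shape_f, size_f = _channel_fits(
        parent, sub_set.coords, tol, max_iter, allow_reflection
    )
    return (ProcrustesFit(pss=1.0 - shape_f, fit=shape_f),
            ProcrustesFit(pss=1.0 - size_f, fit=size_f))


class LandmarkSamplingCurve(BaseEstimator):
    """Scikit-learn style estimator for landmark sampling evaluation curves.

    ``fit(X)`` runs the resampling analysis on a complete landmark dataset
    and exposes the curves as fitted attributes.

    Parameters
    ----------
    n_iterations : int, default 1000
        Rounds of random subsampling.
    thresholds : tuple of float
        Median-fit thresholds summarized in ``threshold_table_``.
    random_state : int or None
        Seed for the subsampling permutations; a fixed seed makes results
        bit-identical across runs.
    n_dims : int, optional
        Needed only for flat (n, p*d) matrix input.
    tol, max_iter, allow_reflection
        Alignment settings, passed to the Procrustes machinery.
    show_progress : bool
        Print completed-iteration counts while fitting.

    Attributes
    ----------
    curves_ : SamplingCurves
    landmark_counts_ : (p-2,) int array, k = 3 ... p.
    shape_fits_, size_fits_ : (n_iterations, p-2) fit matrices.
    shape_median_, size_median_ : column-wise medians.
    threshold_table_ : dict threshold -> {"shape": k, "size": k}.
    landmark_orders_ : (n_iterations, p) permutations used.
    """

    def __init__(self, n_iterations: int = 1000,
                 thresholds=DEFAULT_THRESHOLDS,
                 random_state: int | None = None,
                 n_dims: int | None = None,
                 tol: float = 1e-10, max_iter: int = 100,
                 allow_reflection: bool = True,
                 show_progress: bool = False):
        self.n_iterations = n_iterations
        self.thresholds = thresholds
        self.random_state = random_state
        self.n_dims = n_dims
        self.tol = tol
        self.max_iter = max_iter
        self.allow_reflection = allow_reflection
        self.show_progress = show_progress

    def fit(self, X, y=None):
        spec = SamplingSpec(
            n_iterations=self.n_iterations,
            seed=self.random_state,
            thresholds=tuple(self.thresholds),
        )
        curves = lasec(
            X, spec, n_dims=self.n_dims, tol=self.tol,
            max_iter=self.max_iter, allow_reflection=self.allow_reflection,
            show_progress=self.show_progress,
        )
        self.curves_ = curves
        self.landmark_counts_ = curves.landmark_counts
        self.shape_fits_ = curves.shape_fits
        self.size_fits_ = curves.size_fits
        self.shape_median_ = curves.shape_median
        self.size_median_ = curves.size_median
        self.threshold_table_ = curves.threshold_table
        self.landmark_orders_ = curves.landmark_orders
        return self

    def landmarks_at_threshold(self, threshold: float,
                               channel: str = "shape") -> int | None:
        if not hasattr(self, "curves_"):
            raise RuntimeError("LandmarkSamplingCurve is not fitted")
        return landmarks_at_threshold(self.curves_, threshold, channel)
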
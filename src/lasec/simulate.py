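"""Multivariate-normal coordinate simulator and simulation-study driver.

Each simulated specimen is an independent draw of a ``p * d`` vector from a
zero-mean multivariate normal with a compound-symmetric covariance matrix — a
common variance on the diagonal and one shared covariance between every pair
of coordinate variables — reshaped to a (p, d) configuration.  The point
clouds are raw in the sense required downstream: unaligned and complete.

A property of the global compound-symmetric structure worth knowing: the
shared component is the all-ones direction across coordinate variables, which
lies inside the per-specimen translation subspace.  Generalized Procrustes
alignment removes it, so after centering the effective coordinate covariance
is isotropic with variance ``variance - covariance``; the covariance level
rescales the cloud but leaves sampling-curve shapes essentially unchanged.
"""

from __future__ import annotations

import numpy as np

from .containers import (
    LandmarkConfigurationSet,
    SamplingCurves,
    SamplingSpec,
    SimulationSpec,
)
from .engine import lasec

__all__ = ["sim_coord", "simulation_grid"]


def _compound_symmetric_cholesky(q: int, variance: float,
                                 covariance: float) -> np.ndarray:
    sigma = np.full((q, q), covariance)
    np.fill_diagonal(sigma, variance)
    return np.linalg.cholesky(sigma)


def sim_coord(spec: SimulationSpec | None = None, **kwargs) -> LandmarkConfigurationSet:
    """Draw a synthetic landmark dataset from the compound-symmetric model.

    Either pass a :class:`SimulationSpec` or its fields as keyword arguments::

        sim_coord(n_specimens=10, n_landmarks=40, n_dims=2,
                  covariance=0.1, seed=1)

    Sampling applies the Cholesky factor of the covariance matrix to i.i.d.
    standard-normal draws; identical seeds give identical datasets.
    """
    if spec is None:
        spec = SimulationSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a SimulationSpec or keyword fields, not both")
    q = spec.n_landmarks * spec.n_dims
    chol = _compound_symmetric_cholesky(q, spec.variance, spec.covariance)
    rng = np.random.default_rng(spec.seed)
    flat = rng.standard_normal((spec.n_specimens, q)) @ chol.T
    coords = flat.reshape(spec.n_specimens, spec.n_landmarks, spec.n_dims)
    return LandmarkConfigurationSet(
        coords=coords,
        specimen_ids=tuple(f"sim_{i}" for i in range(spec.n_specimens)),
        landmark_ids=tuple(f"lm_{j}" for j in range(spec.n_landmarks)),
    )


def simulation_grid(
    specimen_counts,
    landmark_counts,
    n_dims: int = 2,
    covariance: float = 0.1,
    sampling: SamplingSpec | None = None,
    *,
    variance: float = 1.0,
    show_progress: bool = False,
) -> dict[tuple[int, int], SamplingCurves]:
    """Run the sampling-curve analysis over a grid of simulated datasets.

    For every (n_specimens, n_landmarks) pair a dataset is simulated and
    analyzed; the master seed in ``sampling`` deterministically spawns
    independent substreams for each grid cell (one for the data draw, one for
    the subsampling), so the whole study is reproducible from a single seed.
    """
    sampling = sampling or SamplingSpec()
    master = np.random.SeedSequence(sampling.seed)
    out: dict[tuple[int, int], SamplingCurves] = {}
    for n in specimen_counts:
        for p in landmark_counts:
            data_ss, lasec_ss = master.spawn(2)
            data = sim_coord(SimulationSpec(
                n_specimens=int(n), n_landmarks=int(p), n_dims=n_dims,
                covariance=covariance, variance=variance,
                seed=int(data_ss.generate_state(1)[0] & 0x7FFFFFFF),
            ))
            cell_spec = SamplingSpec(
                n_iterations=sampling.n_iterations,
                seed=int(lasec_ss.generate_state(1)[0] & 0x7FFFFFFF),
                thresholds=sampling.thresholds,
            )
            if show_progress:
                print(f"grid cell: {n} specimens x {p} landmarks ({n_dims}-D)")
            out[(int(n), int(p))] = lasec(data, cell_spec,
                                          show_progress=show_progress)
    return out
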
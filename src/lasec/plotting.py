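"""Sampling-curve figures and tidy CSV exports.

Figures follow the conventional rarefaction-curve look: every subsampling
iteration is a thin gray trajectory of fit against the number of landmarks,
the median trajectory is a thick dark line, and the landmark counts at which
the median first reaches the summary thresholds are annotated as text.
"""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")  # file output only; no display required
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .containers import SamplingCurves
from .engine import landmarks_at_threshold

__all__ = [
    "plot_sampling_curves",
    "fits_long_frame",
    "median_frame",
    "threshold_frame",
    "write_tables",
]

#: Output filenames for the two sampling-curve figures (extension varies).
SHAPE_FIGURE_STEM = "LaSEC_SamplingCurve_Shape"
SIZE_FIGURE_STEM = "LaSEC_SamplingCurve_Size"


def _plot_channel(curves: SamplingCurves, fits: np.ndarray,
                  median: np.ndarray, channel: str, path: str) -> None:
    k = curves.landmark_counts
    fig, ax = plt.subplots(figsize=(6.0, 4.5))
    marker = "o" if len(k) == 1 else None  # single-k data would be invisible
    for row in fits:
        ax.plot(k, row, color="0.75", lw=0.5, marker=marker, zorder=1)
    ax.plot(k, median, color="0.1", lw=2.5, marker=marker, zorder=2,
            label="median fit")
    texts = []
    for t in curves.spec.thresholds:
        hit = landmarks_at_threshold(curves, t, channel)
        if hit is not None:
            texts.append(f"{t:.2f}: {hit}")
    if texts:
        ax.text(0.98, 0.05, "\n".join(texts), transform=ax.transAxes,
                ha="right", va="bottom", fontsize=9)
    ax.set_xlabel("number of landmarks sampled")
    ax.set_ylabel(f"fit (1 − PSS), {channel}")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower right" if not texts else "upper left", frameon=False)
    fig.tight_layout()
    # suppress the creation timestamp so repeated runs are bit-identical
    metadata = {"CreationDate": None} if path.endswith(".pdf") else None
    fig.savefig(path, metadata=metadata)
    plt.close(fig)


def plot_sampling_curves(curves: SamplingCurves, output_dir,
                         image_format: str = "pdf") -> tuple[str, str]:
    """Write the shape and size sampling-curve figures; returns their paths."""
    os.makedirs(output_dir, exist_ok=True)
    shape_path = os.path.join(output_dir, f"{SHAPE_FIGURE_STEM}.{image_format}")
    size_path = os.path.join(output_dir, f"{SIZE_FIGURE_STEM}.{image_format}")
    _plot_channel(curves, curves.shape_fits, curves.shape_median, "shape",
                  shape_path)
    _plot_channel(curves, curves.size_fits, curves.size_median, "size",
                  size_path)
    return shape_path, size_path


def fits_long_frame(curves: SamplingCurves) -> pd.DataFrame:
    """Tidy per-iteration fits: (iteration, n_landmarks, shape_fit, size_fit)."""
    n_iter, n_k = curves.shape_fits.shape
    return pd.DataFrame({
        "iteration": np.repeat(np.arange(n_iter), n_k),
        "n_landmarks": np.tile(curves.landmark_counts, n_iter),
        "shape_fit": curves.shape_fits.ravel(),
        "size_fit": curves.size_fits.ravel(),
    })


def median_frame(curves: SamplingCurves) -> pd.DataFrame:
    return pd.DataFrame({
        "n_landmarks": curves.landmark_counts,
        "shape_median": curves.shape_median,
        "size_median": curves.size_median,
    })


def threshold_frame(curves: SamplingCurves) -> pd.DataFrame:
    records = []
    for t, entry in curves.threshold_table.items():
        for channel in ("shape", "size"):
            records.append({"channel": channel, "threshold": t,
                            "n_landmarks": entry[channel]})
    return pd.DataFrame.from_records(records)


def write_tables(curves: SamplingCurves, output_dir) -> dict[str, str]:
    """Write the three CSV tables; every figure annotation is recomputable
    from these alone."""
    os.makedirs(output_dir, exist_ok=True)
    paths = {
        "fits": os.path.join(output_dir, "LaSEC_Fits.csv"),
        "median": os.path.join(output_dir, "LaSEC_MedianFit.csv"),
        "thresholds": os.path.join(output_dir, "LaSEC_Thresholds.csv"),
    }
    fits_long_frame(curves).to_csv(paths["fits"], index=False,
                                   float_format="%.17g")
    median_frame(curves).to_csv(paths["median"], index=False,
                                float_format="%.17g")
    threshold_frame(curves).to_csv(paths["thresholds"], index=False)
    return paths
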
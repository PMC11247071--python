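"""Projection-domain bootstrap: reduced-angle, reduced-time realizations.

From a single time-binned acquisition, noise realizations of shorter virtual
acquisitions are generated by, for every retained angle and every pixel
independently, summing k time bins drawn uniformly with replacement from that
pixel's bin sequence, where k = total_time / num_projections in bin units.
Pixels (and angles) are treated as statistically independent; bin values are
summed as floating point without rounding, since corrected list-mode data
need not be integer.
"""

from __future__ import annotations

import warnings

import numpy as np

from .acquisition import ProjectionSet, TimeBinnedProjections

__all__ = ["subsample_angles", "bootstrap_projections"]


def subsample_angles(num_available: int, num_projections: int) -> np.ndarray:
    """Evenly strided angle indices {0, s, 2s, ...} with s = N_avail / N."""
    if num_projections < 1 or num_available < 1:
        raise ValueError("projection counts must be positive")
    if num_available % num_projections != 0:
        raise ValueError(
            f"{num_projections} projections do not evenly divide the "
            f"{num_available} available angles"
        )
    stride = num_available // num_projections
    return np.arange(0, num_available, stride)


def bootstrap_projections(
    tb: TimeBinnedProjections,
    num_projections: int,
    total_time_min: float,
    n_realizations: int = 32,
    rng_seed: int = 0,
) -> list[ProjectionSet]:
    """Bootstrap noise realizations of a reduced acquisition.

    Parameters
    ----------
    tb
        Time-binned base acquisition (the list-mode surrogate).
    num_projections
        Number of retained angles; must evenly divide the available angles.
    total_time_min
        Total virtual acquisition time in minutes; k = total_time /
        num_projections must be an integer number of bins.
    n_realizations
        Number of independent bootstrap realizations (default 32).

    Returns
    -------
    list of ProjectionSet, one per realization, each with
    ``time_per_projection_s = total_time / num_projections`` (virtual time).
    """
    if n_realizations < 1:
        raise ValueError("need at least one realization")
    total_time_s = total_time_min * 60.0
    k_float = total_time_s / num_projections / tb.bin_duration_s
    k = int(round(k_float))
    if abs(k_float - k) > 1e-9 or k < 1:
        raise ValueError(
            f"time per projection ({total_time_s / num_projections} s) is not a "
            f"positive integer number of {tb.bin_duration_s} s bins"
        )
    n_bins = tb.num_bins
    if k > 2 * n_bins:
        warnings.warn(
            f"drawing {k} bins per pixel from only {n_bins} available; the "
            "bootstrap extrapolates far beyond the acquired time",
            stacklevel=2,
        )
    idx = subsample_angles(tb.angles_deg.size, num_projections)
    angles = tb.angles_deg[idx]

    n_angles = idx.size
    nu, nv = tb.bins.shape[1:3]
    npix = nu * nv
    ss = np.random.SeedSequence(rng_seed)
    children = ss.spawn(n_realizations)

    out: list[ProjectionSet] = []
    for r in range(n_realizations):
        rng = np.random.default_rng(children[r])
        counts = np.empty((n_angles, nu, nv))
        for j, a in enumerate(idx):
            flat = tb.bins[a].reshape(npix, n_bins)
            draws = rng.integers(0, n_bins, size=(npix, k))
            counts[j] = (
                np.take_along_axis(flat, draws, axis=1)
                .sum(axis=1, dtype=np.float64)
                .reshape(nu, nv)
            )
        out.append(
            ProjectionSet(
                counts,
                angles,
                time_per_projection_s=total_time_s / num_projections,
                provenance=f"bootstrap[{r}]",
                seed=rng_seed,
            )
        )
    return out
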
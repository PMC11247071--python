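"""Synthetic SPECT acquisition: projection formation, scatter, Poisson noise.

This module stands in for both a physical list-mode acquisition and a photon
transport simulation.  It produces either full-time projection sets or the
1-s time-binned surrogate of list-mode data that the bootstrap module
resamples.  Scatter is modelled as an additive component obtained by
convolving the primary projections with a broad Gaussian, scaled so that the
scatter-to-total ratio of a uniform field equals the configured scatter
fraction (an effective stand-in for model-based scatter estimation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .phantoms import ActivityMap, AttenuationMap
from .projector import Projector, forward_project
from .system import SystemModel

__all__ = [
    "ProjectionSet",
    "TimeBinnedProjections",
    "uniform_angles",
    "scatter_component",
    "add_scatter",
    "simulate_acquisition",
    "simulate_time_binned",
    "realize_poisson",
    "anchor_sensitivity",
]


def uniform_angles(num_projections: int) -> np.ndarray:
    """Angles k*360/N, k = 0..N-1 (degrees)."""
    if num_projections < 1:
        raise ValueError("need at least one projection")
    return np.arange(num_projections) * 360.0 / num_projections


@dataclass
class ProjectionSet:
    """Ordered projection images with acquisition metadata.

    ``counts`` has shape (n_angles, nu, nv). Values may be counts or, for
    noiseless data, expected counts; ``time_per_projection_s`` is virtual
    (single-head) time.
    """

    counts: np.ndarray
    angles_deg: np.ndarray
    time_per_projection_s: float
    energy_window: str = "15% window at 208 keV"
    provenance: str = "simulated"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.counts.ndim != 3 or self.counts.shape[0] != self.angles_deg.size:
            raise ValueError("counts must be (n_angles, nu, nv) matching angles")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.time_per_projection_s <= 0:
            raise ValueError("time per projection must be positive")
        if self.angles_deg.size > 1:
            spacing = np.diff(self.angles_deg)
            if np.any(spacing <= 0) or not np.allclose(
                spacing, 360.0 / self.angles_deg.size
            ):
                raise ValueError("angles must be uniform over 360 degrees")

    @property
    def num_projections(self) -> int:
        return self.angles_deg.size

    @property
    def total_time_s(self) -> float:
        return self.time_per_projection_s * self.num_projections

    def count_rates(self) -> np.ndarray:
        return self.counts / self.time_per_projection_s


@dataclass
class TimeBinnedProjections:
    """Per-angle, per-pixel 1-s count bins — the list-mode surrogate."""

    bins: np.ndarray  # (n_angles, nu, nv, n_bins), float32
    angles_deg: np.ndarray
    bin_duration_s: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.bins.ndim != 4 or self.bins.shape[0] != self.angles_deg.size:
            raise ValueError("bins must be (n_angles, nu, nv, n_bins)")
        if np.any(self.bins < 0):
            raise ValueError("bins must be nonnegative")

    @property
    def num_bins(self) -> int:
        return self.bins.shape[3]

    def to_projection_set(self) -> ProjectionSet:
        """Sum over time bins: the full-time acquisition."""
        return ProjectionSet(
            counts=self.bins.sum(axis=3, dtype=np.float64),
            angles_deg=self.angles_deg,
            time_per_projection_s=self.num_bins * self.bin_duration_s,
            provenance="time-binned sum",
            seed=self.seed,
        )


def scatter_component(primary: np.ndarray, system: SystemModel) -> np.ndarray:
    """Additive scatter term for primary projections (same units as input)."""
    sf = system.scatter_fraction
    if sf == 0.0:
        return np.zeros_like(primary)
    sigma_px = system.scatter_kernel_mm / system.pixel_size_mm
    ratio = sf / (1.0 - sf)
    out = np.empty_like(primary)
    for i in range(primary.shape[0]):
        out[i] = gaussian_filter(primary[i], sigma_px, mode="constant", truncate=4.0)
    return ratio * out


def add_scatter(primary: np.ndarray, system: SystemModel) -> np.ndarray:
    """Total (primary + scatter) projections."""
    return primary + scatter_component(primary, system)


def _total_rate(
    activity: ActivityMap,
    attenuation: AttenuationMap | None,
    system: SystemModel,
    angles_deg,
) -> np.ndarray:
    primary = forward_project(activity, attenuation, system, angles_deg)
    return add_scatter(primary, system)


def simulate_acquisition(
    activity: ActivityMap,
    attenuation: AttenuationMap | None,
    system: SystemModel,
    num_projections: int,
    total_time_s: float,
    rng_seed: int,
    rate: np.ndarray | None = None,
) -> ProjectionSet:
    """Poisson projection set for a total (virtual) acquisition time.

    ``rate`` may carry precomputed total count-rate projections (counts/s,
    including scatter) to avoid re-projection across noise realizations.
    """
    if total_time_s <= 0:
        raise ValueError("total acquisition time must be positive")
    angles = uniform_angles(num_projections)
    if rate is None:
        rate = _total_rate(activity, attenuation, system, angles)
    t_per = total_time_s / num_projections
    rng = np.random.default_rng(rng_seed)
    counts = rng.poisson(rate * t_per).astype(float)
    return ProjectionSet(counts, angles, t_per, provenance="simulated", seed=rng_seed)


def realize_poisson(
    rate: np.ndarray, angles_deg, time_per_projection_s: float, rng_seed: int
) -> ProjectionSet:
    """Poisson realization of precomputed count-rate projections."""
    if time_per_projection_s <= 0:
        raise ValueError("time per projection must be positive")
    rng = np.random.default_rng(rng_seed)
    counts = rng.poisson(rate * time_per_projection_s).astype(float)
    return ProjectionSet(
        counts, angles_deg, time_per_projection_s, provenance="simulated", seed=rng_seed
    )


def simulate_time_binned(
    activity: ActivityMap,
    attenuation: AttenuationMap | None,
    system: SystemModel,
    num_projections: int = 120,
    time_per_projection_s: int = 180,
    rng_seed: int = 0,
) -> TimeBinnedProjections:
    """Independent Poisson 1-s bins per angle and pixel.

    The bin sums are distributed as a full-time acquisition; the default
    protocol (120 projections, 180 s each) gives 180 bins per angle.
    """
    if time_per_projection_s != int(time_per_projection_s) or time_per_projection_s <= 0:
        raise ValueError("time per projection must be a positive integer number of seconds")
    n_bins = int(time_per_projection_s)
    angles = uniform_angles(num_projections)
    rate = _total_rate(activity, attenuation, system, angles)
    ss = np.random.SeedSequence(rng_seed)
    children = ss.spawn(num_projections)
    bins = np.empty(rate.shape + (n_bins,), dtype=np.float32)
    for i in range(num_projections):
        rng = np.random.default_rng(children[i])
        lam = rate[i] * float(1.0)
        bins[i] = rng.poisson(lam[..., None], size=lam.shape + (n_bins,)).astype(
            np.float32
        )
    return TimeBinnedProjections(bins, angles, 1.0, seed=rng_seed)


def anchor_sensitivity(
    activity: ActivityMap,
    attenuation: AttenuationMap | None,
    system: SystemModel,
    target_rate_cps: float = 700.0,
    num_projections: int = 120,
) -> SystemModel:
    """Return a system whose aggregate count rate matches ``target_rate_cps``.

    The aggregate rate is the mean over projection angles of the total
    counts/s on the detector (scatter included), evaluated for the given
    phantom; the returned system has its sensitivity rescaled accordingly.
    """
    angles = uniform_angles(num_projections)
    rate = _total_rate(activity, attenuation, system, angles)
    agg = float(rate.sum(axis=(1, 2)).mean())
    if agg <= 0:
        raise ValueError("phantom produces no counts; cannot anchor sensitivity")
    return system.with_(
        sensitivity_cps_per_MBq=system.sensitivity_cps_per_MBq * target_rate_cps / agg
    )
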
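"""VOI activity quantification and bias/precision statistics.

For each combination of phantom region, acquisition setting and
reconstruction setting, the mean activity concentration in a
volume-preserving VOI is estimated on every noise realization, and the
realizations are summarized into the two study endpoints:

* absolute mean relative error  |C_est_bar / C_ref - 1|   (bias axis), and
* coefficient of variation      CV = s / C_est_bar        (precision axis),

with s the sample standard deviation (n-1 denominator) over realizations.
Settings where the mean estimate is zero leave the CV undefined and are
flagged invalid.  Outliers — estimates deviating more than 50 % from the
median, or a zero median altogether — are flagged for reporting but kept in
the summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .voxelize import make_voi_mask  # re-exported: VOIs share the phantom voxelizer

__all__ = [
    "QuantRecord",
    "make_voi_mask",
    "estimate_concentration",
    "summarize_realizations",
    "detect_outliers",
    "filter_for_plots",
]


@dataclass
class QuantRecord:
    """Summary of one (phantom, VOI, acquisition, reconstruction) cell."""

    phantom: str
    voi: str
    num_projections: int
    total_time_min: float
    num_subsets: int
    num_iterations: int
    c_est_mean: float          # mean estimated concentration (MBq/mL)
    c_est_sd: float            # sample SD over realizations
    c_ref: float               # reference concentration (MBq/mL)
    n_realizations: int
    cv: float = float("nan")   # s / mean; NaN when undefined
    abs_mean_rel_error: float = float("nan")
    valid: bool = True
    median_zero: bool = False
    n_outliers: int = 0

    @property
    def updates(self) -> int:
        return self.num_subsets * self.num_iterations


def estimate_concentration(calibrated_image: np.ndarray, mask: np.ndarray) -> float:
    """Mean calibrated voxel value (MBq/mL) inside a VOI mask."""
    if not np.any(mask):
        raise ValueError("VOI mask is empty")
    return float(calibrated_image[mask].mean())


def detect_outliers(estimates) -> tuple[np.ndarray, bool]:
    """Flag estimates deviating more than 50 % from the median.

    Returns (per-estimate flags, median_zero). With a zero median, relative
    deviation is undefined; the setting-level flag is raised instead and no
    per-estimate flags are set.
    """
    x = np.asarray(estimates, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two estimates")
    med = float(np.median(x))
    if med == 0.0:
        return np.zeros(x.size, dtype=bool), True
    return np.abs(x / med - 1.0) > 0.5, False


def summarize_realizations(
    estimates,
    c_ref: float,
    *,
    phantom: str = "",
    voi: str = "",
    num_projections: int = 0,
    total_time_min: float = 0.0,
    num_subsets: int = 0,
    num_iterations: int = 0,
) -> QuantRecord:
    """Bias/precision summary of per-realization concentration estimates."""
    x = np.asarray(estimates, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two realizations")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    flags, median_zero = detect_outliers(x)
    rec = QuantRecord(
        phantom=phantom,
        voi=voi,
        num_projections=num_projections,
        total_time_min=total_time_min,
        num_subsets=num_subsets,
        num_iterations=num_iterations,
        c_est_mean=mean,
        c_est_sd=sd,
        c_ref=c_ref,
        n_realizations=int(x.size),
        median_zero=median_zero,
        n_outliers=int(flags.sum()),
    )
    if mean == 0.0:
        rec.valid = False  # CV undefined
        return rec
    rec.cv = sd / mean
    rec.abs_mean_rel_error = abs(mean / c_ref - 1.0)
    return rec


def filter_for_plots(records: list[QuantRecord]) -> list[QuantRecord]:
    """Inclusion rule for the Pareto plots.

    Keeps valid records with at least two iterations and at least 16 updates.
    """
    return [
        r
        for r in records
        if r.valid and r.num_iterations >= 2 and r.updates >= 16
    ]
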
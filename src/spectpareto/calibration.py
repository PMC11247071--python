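"""Reconstruction-setting-specific calibration factors.

A uniform activity-filled cylinder of known concentration is projected
without noise (the analogue of a long calibration acquisition), reconstructed
with every reconstruction setting under study, and the factor

    factor = reference concentration / mean reconstructed VOI signal

is tabulated per (projections, subsets, iterations).  Applying the factor to
an image reconstructed with the same setting converts count-rate
concentration to activity concentration in MBq/mL; by construction it
reproduces the reference concentration exactly on the calibration data.

The VOI is a large cylinder coaxial with the phantom with radius 60 % of the
phantom radius and length chosen to reach the target VOI volume (375 mL or
1953 mL in the study protocols); only the VOI volume is protocol-specified,
the aspect ratio is a documented choice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .acquisition import ProjectionSet, scatter_component, uniform_angles
from .osem import OSEMModel, ReconScheme
from .phantoms import Grid, make_cylinder_phantom
from .projector import Projector, forward_project
from .shapes import Cylinder
from .system import SystemModel
from .voxelize import make_voi_mask

__all__ = [
    "compute_calibration_factor",
    "calibration_voi_mask",
    "calibrate_all",
    "factor_lookup",
]


def compute_calibration_factor(
    image: np.ndarray, voi_mask: np.ndarray, ref_concentration: float
) -> float:
    """Calibration factor from a reconstructed uniform-phantom image."""
    if not voi_mask.any():
        raise ValueError("calibration VOI mask is empty")
    mean_signal = float(image[voi_mask].mean())
    if mean_signal <= 0:
        raise ValueError("mean VOI signal is zero; calibration factor undefined")
    return ref_concentration / mean_signal


def calibration_voi_mask(
    grid: Grid,
    voi_volume_mL: float,
    phantom_radius_mm: float = 108.0,
    radius_ratio: float = 0.6,
) -> np.ndarray:
    """Central cylindrical VOI of the requested volume, coaxial with the phantom."""
    r = radius_ratio * phantom_radius_mm
    length = voi_volume_mL * 1e3 / (np.pi * r**2)
    voi = Cylinder((0.0, 0.0, 0.0), r, length)
    return make_voi_mask(voi, grid, target_volume_mL=voi_volume_mL)


def calibrate_all(
    schemes: list[ReconScheme],
    grid: Grid,
    system: SystemModel,
    voi_volume_mL: float = 375.0,
    radius_mm: float = 108.0,
    length_mm: float = 186.0,
    concentration: float = 22.8e-3,
) -> pd.DataFrame:
    """Calibration factor table for every reconstruction scheme.

    Projections are noiseless (no Poisson draw) with matched scatter
    compensation. One reconstruction per (projections, subsets) pair at the
    maximal iteration count serves all lower iteration counts through the
    per-iteration snapshots.

    Returns
    -------
    DataFrame with columns num_projections, num_subsets, num_iterations,
    factor.
    """
    activity, attenuation = make_cylinder_phantom(
        grid, radius_mm=radius_mm, length_mm=length_mm, concentration=concentration
    )
    voi = calibration_voi_mask(grid, voi_volume_mL, phantom_radius_mm=radius_mm)

    rows = []
    by_n: dict[int, list[ReconScheme]] = {}
    for s in schemes:
        by_n.setdefault(s.num_projections, []).append(s)
    for n, group in sorted(by_n.items()):
        angles = uniform_angles(n)
        primary = forward_project(activity, attenuation, system, angles)
        scat = scatter_component(primary, system)
        # virtual 1 s per projection: counts equal rates, noise-free
        pset = ProjectionSet(
            primary + scat, angles, 1.0, provenance="calibration (noise-free)"
        )
        projector = Projector(grid, system, angles, attenuation)
        by_subsets: dict[int, int] = {}
        for s in group:
            by_subsets[s.num_subsets] = max(
                by_subsets.get(s.num_subsets, 0), s.num_iterations
            )
        wanted = {(s.num_subsets, s.num_iterations) for s in group}
        for n_sub, max_iter in sorted(by_subsets.items()):
            model = OSEMModel(
                pset, attenuation, system, scatter_rate=scat, projector=projector
            )
            res = model.fit(ReconScheme(n, n_sub, max_iter))
            for it in range(1, max_iter + 1):
                if (n_sub, it) not in wanted:
                    continue
                factor = compute_calibration_factor(
                    res.iterate(it), voi, concentration
                )
                rows.append(
                    {
                        "num_projections": n,
                        "num_subsets": n_sub,
                        "num_iterations": it,
                        "factor": factor,
                    }
                )
    return pd.DataFrame(rows)


def factor_lookup(table: pd.DataFrame) -> dict[tuple[int, int, int], float]:
    """Map (projections, subsets, iterations) -> calibration factor."""
    return {
        (int(r.num_projections), int(r.num_subsets), int(r.num_iterations)): float(
            r.factor
        )
        for r in table.itertuples()
    }
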
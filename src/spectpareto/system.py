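"""Gamma-camera system description for the analytic projector.

The camera is modelled as a parallel-hole (parallel-beam) system with a
Gaussian collimator-detector response whose width grows linearly with the
source-to-collimator distance,

    sigma(d) = sqrt(sigma0^2 + (slope * d)^2),

an overall sensitivity (counts/s per MBq in the photopeak window), and an
additive scatter component expressed as an effective scatter fraction with a
broad Gaussian kernel. Defaults are representative of a medium-energy
collimator imaging the 208 keV line of Lu-177; they are configuration, not
measured values of any particular camera.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["SystemModel"]


@dataclass(frozen=True)
class SystemModel:
    pixel_size_mm: float = 4.42
    num_pixels: int = 128
    orbit_radius_mm: float = 250.0
    sigma0_mm: float = 1.7          # intrinsic resolution (sigma)
    blur_slope: float = 0.043       # mm of blur sigma per mm distance
    sensitivity_cps_per_MBq: float = 10.0
    scatter_fraction: float = 0.2   # scatter / total in the photopeak window
    scatter_kernel_mm: float = 40.0  # sigma of the effective scatter kernel

    def __post_init__(self) -> None:
        if self.pixel_size_mm <= 0 or self.num_pixels < 1:
            raise ValueError("detector geometry invalid")
        if self.sensitivity_cps_per_MBq <= 0:
            raise ValueError("sensitivity must be positive")
        if not (0.0 <= self.scatter_fraction < 1.0):
            raise ValueError("scatter_fraction must be in [0, 1)")
        if self.sigma0_mm < 0 or self.blur_slope < 0:
            raise ValueError("PSF parameters must be nonnegative")

    def sigma_at(self, distance_mm) -> np.ndarray:
        """Blur sigma (mm) at source-to-collimator distance d >= 0."""
        d = np.maximum(np.asarray(distance_mm, dtype=float), 0.0)
        return np.sqrt(self.sigma0_mm**2 + (self.blur_slope * d) ** 2)

    def with_(self, **changes) -> "SystemModel":
        params = asdict(self)
        params.update(changes)
        return SystemModel(**params)
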
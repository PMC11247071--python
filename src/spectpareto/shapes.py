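"""Analytic shape primitives used for phantom regions and volumes of interest.

All coordinates are in millimetres in the world frame of a :class:`~spectpareto.phantoms.Grid`
(origin at the grid centre unless stated otherwise).  Shapes expose a vectorized
inside-test and an axis-aligned bounding box, which is all the voxelization
machinery needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Sphere", "Ellipsoid", "Cylinder", "EllipticalCylinder"]


@dataclass(frozen=True)
class Sphere:
    """Sphere given by centre (mm) and radius (mm)."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"sphere radius must be positive, got {self.radius}")

    @classmethod
    def from_volume(cls, center, volume_mL: float) -> "Sphere":
        """Sphere of a given volume in mL (1 mL = 1000 mm^3)."""
        if volume_mL <= 0:
            raise ValueError("volume must be positive")
        r = (3.0 * volume_mL * 1e3 / (4.0 * np.pi)) ** (1.0 / 3.0)
        return cls(tuple(center), r)

    @property
    def volume_mL(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3 / 1e3

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = points - np.asarray(self.center)
        return (d**2).sum(axis=-1) <= self.radius**2

    def bounding_box(self):
        c = np.asarray(self.center, dtype=float)
        r = self.radius
        return c - r, c + r


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid with semi-axes (mm)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("ellipsoid semi-axes must be positive")

    @property
    def volume_mL(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c / 1e3

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = (points - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return (d**2).sum(axis=-1) <= 1.0

    def bounding_box(self):
        c = np.asarray(self.center, dtype=float)
        s = np.asarray(self.semi_axes, dtype=float)
        return c - s, c + s


@dataclass(frozen=True)
class Cylinder:
    """Circular cylinder with axis parallel to z."""

    center: tuple[float, float, float]
    radius: float
    length: float

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0:
            raise ValueError(
                f"cylinder radius/length must be positive, got r={self.radius}, L={self.length}"
            )

    @property
    def volume_mL(self) -> float:
        return np.pi * self.radius**2 * self.length / 1e3

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = points - np.asarray(self.center)
        in_plane = d[..., 0] ** 2 + d[..., 1] ** 2 <= self.radius**2
        axial = np.abs(d[..., 2]) <= self.length / 2.0
        return in_plane & axial

    def bounding_box(self):
        c = np.asarray(self.center, dtype=float)
        ext = np.array([self.radius, self.radius, self.length / 2.0])
        return c - ext, c + ext


@dataclass(frozen=True)
class EllipticalCylinder:
    """Elliptical cylinder (axis parallel to z); body shell of the sphere phantom."""

    center: tuple[float, float, float]
    semi_axis_x: float
    semi_axis_y: float
    length: float

    def __post_init__(self) -> None:
        if self.semi_axis_x <= 0 or self.semi_axis_y <= 0 or self.length <= 0:
            raise ValueError("elliptical cylinder dimensions must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = points - np.asarray(self.center)
        in_plane = (d[..., 0] / self.semi_axis_x) ** 2 + (
            d[..., 1] / self.semi_axis_y
        ) ** 2 <= 1.0
        axial = np.abs(d[..., 2]) <= self.length / 2.0
        return in_plane & axial

    def bounding_box(self):
        c = np.asarray(self.center, dtype=float)
        ext = np.array([self.semi_axis_x, self.semi_axis_y, self.length / 2.0])
        return c - ext, c + ext
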
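"""Voxelized activity and attenuation phantoms.

Three phantoms are provided, mirroring a typical quantitative Lu-177 SPECT
optimization study:

* a NEMA-IEC-like body phantom with six hot spheres (0.52–26.9 mL) in a cold
  water-filled shell, used for bias/precision evaluation;
* uniform activity-filled cylinders used to derive calibration factors;
* a stylized anthropomorphic phantom (ellipsoidal liver, spleen and kidneys,
  three spherical tumours of 2.8, 8.9 and 40.0 mL) with activity
  concentrations representative of Lu-177-DOTA-TATE at 24 h and 168 h after
  administration.

Geometry is defined analytically in millimetres and voxelized with the
volume-preserving rule of :mod:`spectpareto.voxelize`, so every region's
voxel volume is within one voxel of its nominal volume regardless of grid
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .shapes import Cylinder, Ellipsoid, EllipticalCylinder, Sphere
from .voxelize import make_voi_mask

__all__ = [
    "Grid",
    "ActivityMap",
    "AttenuationMap",
    "PhantomSpec",
    "RegionSpec",
    "MU_WATER_208KEV",
    "LU177_HALF_LIFE_DAYS",
    "SPHERE_VOLUMES_ML",
    "TUMOUR_VOLUMES_ML",
    "ORGAN_CONCENTRATIONS",
    "TUMOUR_CONCENTRATIONS",
    "decay_factor",
    "make_sphere_phantom",
    "make_cylinder_phantom",
    "make_anthro_phantom",
]

#: Narrow-beam linear attenuation coefficient of water at 208 keV (cm^-1).
MU_WATER_208KEV = 0.136

#: Physical half-life of Lu-177 in days.
LU177_HALF_LIFE_DAYS = 6.647

#: NEMA-like sphere volumes in mL, ascending (spheres 1..6).
SPHERE_VOLUMES_ML = (0.52, 1.15, 2.72, 5.61, 11.7, 26.9)

#: Tumour volumes in mL (tumours 1..3).
TUMOUR_VOLUMES_ML = (2.8, 8.9, 40.0)

#: Organ activity concentrations (MBq/mL) by time point (h post injection).
ORGAN_CONCENTRATIONS = {
    24: {"liver": 0.14, "spleen": 0.51, "kidney_left": 0.34, "kidney_right": 0.45},
    168: {"liver": 0.040, "spleen": 0.12, "kidney_left": 0.051, "kidney_right": 0.068},
}

#: Tumour activity concentration (MBq/mL) by time point (h post injection).
TUMOUR_CONCENTRATIONS = {24: 1.9, 168: 0.75}


@dataclass(frozen=True)
class Grid:
    """Regular isotropic voxel grid.

    ``origin`` is the world coordinate (mm) of the grid centre; voxel centres
    along axis i are ``origin[i] + (k - (n_i - 1)/2) * voxel_size``.
    """

    shape: tuple[int, int, int]
    voxel_size: float = 4.42
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if len(self.shape) != 3 or min(self.shape) < 8:
            raise ValueError(f"grid shape must be 3-D with all dims >= 8, got {self.shape}")

    @property
    def voxel_volume_mL(self) -> float:
        return self.voxel_size**3 / 1e3

    def axis_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            o + (np.arange(n) - (n - 1) / 2.0) * self.voxel_size
            for n, o in zip(self.shape, self.origin)
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer edges of the grid (mm)."""
        half = np.asarray(self.shape) * self.voxel_size / 2.0
        o = np.asarray(self.origin, dtype=float)
        return o - half, o + half

    def meshgrid(self) -> np.ndarray:
        xs, ys, zs = self.axis_centers()
        return np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)


@dataclass
class ActivityMap:
    """Activity concentration per voxel (MBq/mL) on a grid."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if np.any(self.values < 0):
            raise ValueError("activity concentrations must be nonnegative")

    @property
    def total_activity_MBq(self) -> float:
        return float(self.values.sum() * self.grid.voxel_volume_mL)


@dataclass
class AttenuationMap:
    """Linear attenuation coefficient per voxel (cm^-1) at 208 keV."""

    grid: Grid
    mu: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.shape != self.grid.shape:
            raise ValueError("mu shape does not match grid")
        if np.any(self.mu < 0):
            raise ValueError("attenuation coefficients must be nonnegative")


@dataclass(frozen=True)
class RegionSpec:
    label: str
    shape: object
    volume_mL: float
    concentration: float  # MBq/mL


@dataclass
class PhantomSpec:
    """Declarative description of a phantom: regions with shapes and concentrations."""

    kind: str  # spheres | cylinder | anthro
    regions: list[RegionSpec] = field(default_factory=list)
    timepoint_h: int | None = None

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        for r in self.regions:
            if r.volume_mL <= 0:
                raise ValueError(f"region {r.label} has nonpositive volume")

    def to_yaml(self, path) -> None:
        import dataclasses
        import yaml

        doc = {
            "kind": self.kind,
            "timepoint_h": self.timepoint_h,
            "regions": [
                {
                    "label": r.label,
                    "shape_type": type(r.shape).__name__,
                    "shape": dataclasses.asdict(r.shape),
                    "volume_mL": r.volume_mL,
                    "concentration": r.concentration,
                }
                for r in self.regions
            ],
        }
        from pathlib import Path

        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        import yaml
        from pathlib import Path

        from . import shapes as _shapes

        doc = yaml.safe_load(Path(path).read_text())
        regions = []
        for r in doc.get("regions", []):
            shape_cls = getattr(_shapes, r["shape_type"])
            kwargs = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in r["shape"].items()
            }
            regions.append(
                RegionSpec(
                    r["label"], shape_cls(**kwargs), r["volume_mL"], r["concentration"]
                )
            )
        return cls(doc["kind"], regions, doc.get("timepoint_h"))


def decay_factor(delta_t_days: float) -> float:
    """Radioactive decay factor of Lu-177 over ``delta_t_days`` days."""
    if not np.isfinite(delta_t_days):
        raise ValueError("delta_t must be finite")
    return float(2.0 ** (-delta_t_days / LU177_HALF_LIFE_DAYS))


# Sphere phantom geometry (mm). The shell is an elliptical cylinder
# approximating the NEMA IEC body shape; the six spheres sit on a ring in the
# central transverse plane, as in the physical phantom.
_BODY_SEMI_X = 135.0
_BODY_SEMI_Y = 98.0
_BODY_LENGTH = 180.0
_SPHERE_RING_RADIUS = 57.2


def make_sphere_phantom(
    grid: Grid,
    concentration: float = 5.80,
    sphere_volumes_mL: tuple[float, ...] = SPHERE_VOLUMES_ML,
    mu_water: float = MU_WATER_208KEV,
    background_concentration: float = 0.0,
):
    """Six hot spheres in a cold elliptical-cylinder body.

    Parameters
    ----------
    concentration
        Sphere activity concentration in MBq/mL (default 5.80, the nominal
        fill of the physical phantom at the start of acquisition).

    Returns
    -------
    (ActivityMap, AttenuationMap, dict[label, bool mask])
    """
    body = EllipticalCylinder((0.0, 0.0, 0.0), _BODY_SEMI_X, _BODY_SEMI_Y, _BODY_LENGTH)
    angles = np.deg2rad(30.0 + 60.0 * np.arange(len(sphere_volumes_mL)))
    masks: dict[str, np.ndarray] = {}
    activity = np.zeros(grid.shape, dtype=float)
    for i, (vol, ang) in enumerate(zip(sphere_volumes_mL, angles), start=1):
        c = (
            _SPHERE_RING_RADIUS * np.cos(ang),
            _SPHERE_RING_RADIUS * np.sin(ang),
            0.0,
        )
        sph = Sphere.from_volume(c, vol)
        label = f"sphere{i}"
        try:
            mask = make_voi_mask(sph, grid, target_volume_mL=vol)
        except ValueError as err:
            raise ValueError(f"grid too small for {label} ({vol} mL): {err}") from err
        masks[label] = mask
        activity[mask] = concentration

    pts = grid.meshgrid()
    body_mask = body.contains(pts)
    for label, mask in masks.items():
        body_mask |= mask  # attenuation support must contain activity support
    if background_concentration > 0:
        bg = body_mask.copy()
        for mask in masks.values():
            bg &= ~mask
        activity[bg] = background_concentration
    mu = np.where(body_mask, mu_water, 0.0)
    return ActivityMap(grid, activity), AttenuationMap(grid, mu), masks


def make_cylinder_phantom(
    grid: Grid,
    radius_mm: float = 108.0,
    length_mm: float = 186.0,
    concentration: float = 22.8e-3,
    mu_water: float = MU_WATER_208KEV,
):
    """Uniform activity-filled cylinder (calibration phantom).

    Defaults reproduce the simulated calibration cylinder (radius 10.8 cm,
    length 18.6 cm); the default concentration is the 22.8 kBq/mL fill of the
    physical uniform phantom.
    """
    cyl = Cylinder((0.0, 0.0, 0.0), radius_mm, length_mm)
    try:
        mask = make_voi_mask(cyl, grid, target_volume_mL=cyl.volume_mL)
    except ValueError as err:
        raise ValueError(f"cylinder does not fit in grid: {err}") from err
    activity = np.where(mask, concentration, 0.0)
    mu = np.where(mask, mu_water, 0.0)
    return ActivityMap(grid, activity), AttenuationMap(grid, mu)


# Anthropomorphic phantom geometry (mm): a large ellipsoidal body with
# ellipsoidal organs and three spherical tumours at fixed, documented
# positions chosen so no region touches the body surface or another region.
_ANTHRO_BODY = Ellipsoid((0.0, 0.0, 0.0), (130.0, 90.0, 95.0))
_ANTHRO_ORGANS = {
    "liver": Ellipsoid((40.0, 20.0, 15.0), (75.0, 55.0, 42.0)),
    "spleen": Ellipsoid((-75.0, 30.0, 10.0), (35.0, 25.0, 30.0)),
    "kidney_left": Ellipsoid((-55.0, -45.0, -35.0), (27.0, 20.0, 38.0)),
    "kidney_right": Ellipsoid((55.0, -45.0, -35.0), (27.0, 20.0, 38.0)),
}
_ANTHRO_TUMOUR_CENTERS = ((-20.0, -60.0, 30.0), (20.0, 55.0, -40.0), (-60.0, -20.0, 45.0))


def make_anthro_phantom(
    grid: Grid,
    timepoint_h: int = 24,
    mu_water: float = MU_WATER_208KEV,
    background_concentration: float = 0.0,
):
    """Stylized anthropomorphic phantom at 24 h or 168 h post injection.

    Organ and tumour concentrations follow the printed Lu-177-DOTA-TATE values
    for the requested time point; organ shapes and positions are fixed
    stand-ins (the study geometry is not reproduced exactly). The remainder of
    the body defaults to zero activity, configurable via
    ``background_concentration``.

    Returns
    -------
    (ActivityMap, AttenuationMap, dict[label, bool mask])
    """
    if timepoint_h not in ORGAN_CONCENTRATIONS:
        raise ValueError(
            f"unknown timepoint {timepoint_h} h; supported: {sorted(ORGAN_CONCENTRATIONS)}"
        )
    organ_conc = ORGAN_CONCENTRATIONS[timepoint_h]
    tumour_conc = TUMOUR_CONCENTRATIONS[timepoint_h]

    activity = np.zeros(grid.shape, dtype=float)
    masks: dict[str, np.ndarray] = {}
    for label, shape in _ANTHRO_ORGANS.items():
        mask = make_voi_mask(shape, grid, target_volume_mL=shape.volume_mL)
        masks[label] = mask
        activity[mask] = organ_conc[label]
    for i, (c, vol) in enumerate(zip(_ANTHRO_TUMOUR_CENTERS, TUMOUR_VOLUMES_ML), start=1):
        sph = Sphere.from_volume(c, vol)
        mask = make_voi_mask(sph, grid, target_volume_mL=vol)
        masks[f"tumour{i}"] = mask
        activity[mask] = tumour_conc

    pts = grid.meshgrid()
    body_mask = _ANTHRO_BODY.contains(pts)
    for mask in masks.values():
        body_mask |= mask
    if background_concentration > 0:
        bg = body_mask.copy()
        for mask in masks.values():
            bg &= ~mask
        activity[bg] = background_concentration
    mu = np.where(body_mask, mu_water, 0.0)
    return ActivityMap(grid, activity), AttenuationMap(grid, mu), masks
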
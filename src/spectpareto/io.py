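"""File formats: NIfTI volumes, JSON sidecars, YAML configs, CSV tables."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .acquisition import ProjectionSet
from .phantoms import Grid
from .system import SystemModel

__all__ = [
    "save_volume",
    "load_volume",
    "save_label_masks",
    "save_projection_set",
    "load_projection_set",
    "save_system",
    "load_system",
    "write_table",
]


def _affine(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = grid.voxel_size
    lo, _ = grid.bounds()
    aff[:3, 3] = lo + grid.voxel_size / 2.0  # world coord of voxel (0,0,0)
    return aff


def save_volume(path, values: np.ndarray, grid: Grid) -> Path:
    """Write a grid-shaped volume as NIfTI with mm units in the affine."""
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), _affine(grid))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return Path(path)


def load_volume(path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    vs = float(img.affine[0, 0])
    lo = img.affine[:3, 3] - vs / 2.0
    center = lo + np.asarray(data.shape) * vs / 2.0
    grid = Grid(tuple(int(n) for n in data.shape), vs, tuple(float(c) for c in center))
    return data, grid


def save_label_masks(path_prefix, masks: dict[str, np.ndarray], grid: Grid) -> tuple[Path, Path]:
    """Write region masks as a NIfTI label volume plus a JSON label table."""
    labels = np.zeros(grid.shape, dtype=np.int16)
    table = {}
    for i, (name, mask) in enumerate(masks.items(), start=1):
        labels[mask] = i
        table[i] = name
    vol_path = Path(f"{path_prefix}_labels.nii.gz")
    img = nib.Nifti1Image(labels, _affine(grid))
    nib.save(img, str(vol_path))
    json_path = Path(f"{path_prefix}_labels.json")
    json_path.write_text(json.dumps(table, indent=1, sort_keys=True))
    return vol_path, json_path


def save_projection_set(path_prefix, pset: ProjectionSet) -> tuple[Path, Path]:
    """Projection stack as NIfTI plus a JSON sidecar with acquisition metadata."""
    nii_path = Path(f"{path_prefix}.nii.gz")
    img = nib.Nifti1Image(
        np.asarray(pset.counts, dtype=np.float32).transpose(1, 2, 0), np.eye(4)
    )
    nib.save(img, str(nii_path))
    meta = {
        "angles_deg": pset.angles_deg.tolist(),
        "time_per_projection_s": pset.time_per_projection_s,
        "energy_window": pset.energy_window,
        "provenance": pset.provenance,
        "seed": pset.seed,
    }
    json_path = Path(f"{path_prefix}.json")
    json_path.write_text(json.dumps(meta, indent=1))
    return nii_path, json_path


def load_projection_set(path_prefix) -> ProjectionSet:
    data = np.asarray(nib.load(f"{path_prefix}.nii.gz").dataobj, dtype=float)
    meta = json.loads(Path(f"{path_prefix}.json").read_text())
    return ProjectionSet(
        counts=data.transpose(2, 0, 1),
        angles_deg=np.asarray(meta["angles_deg"]),
        time_per_projection_s=meta["time_per_projection_s"],
        energy_window=meta.get("energy_window", ""),
        provenance=meta.get("provenance", "loaded"),
        seed=meta.get("seed"),
    )


def save_system(path, system: SystemModel) -> Path:
    Path(path).write_text(yaml.safe_dump(asdict(system), sort_keys=True))
    return Path(path)


def load_system(path) -> SystemModel:
    return SystemModel(**yaml.safe_load(Path(path).read_text()))


def write_table(frame, path) -> Path:
    """Deterministic CSV output (fixed float format, no index)."""
    frame.to_csv(path, index=False, float_format="%.12g")
    return Path(path)
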
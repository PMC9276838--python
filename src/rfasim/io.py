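"""File formats: NIfTI volumes, scene/config YAML, reports, meshes.

Volumes (CT-like intensity stacks, temperature or damage snapshots, label
masks) use NIfTI via nibabel with the affine carrying voxel spacing and
origin in mm.  Scene and run configuration round-trip through a small
human-readable YAML schema; surfaces go through trimesh's standard mesh
writers (STL/PLY); reports are JSON/CSV.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional, Tuple

import nibabel as nib
import numpy as np
import yaml


class FormatError(ValueError):
    pass


# ----------------------------------------------------------------------------
# NIfTI volumes


def write_nifti(path, volume: np.ndarray, spacing, origin=(0.0, 0.0, 0.0)):
    spacing = np.broadcast_to(np.asarray(spacing, float), (3,))
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    affine[:3, 3] = np.asarray(origin, float)
    nib.save(nib.Nifti1Image(np.asarray(volume, np.float32), affine), str(path))


def read_nifti(path) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (volume, spacing_mm, origin_mm)."""
    img = nib.load(str(path))
    affine = img.affine
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    origin = affine[:3, 3].copy()
    return np.asarray(img.get_fdata()), spacing, origin


# ----------------------------------------------------------------------------
# config / scene descriptions


def save_run_config(path, config):
    with open(path, "w") as f:
        yaml.safe_dump(_to_plain(dataclasses.asdict(config)), f,
                       sort_keys=False)


def load_run_config(path):
    from .damage import DamageParameters
    from .pipeline import ConfigError, RunConfig
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    if not isinstance(data, dict):
        raise ConfigError("run config must be a mapping")
    if "damage" in data and isinstance(data["damage"], dict):
        data["damage"] = DamageParameters(**data["damage"])
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_electrode(path, spec):
    """Electrode spec as human-readable YAML (key/value + point lists)."""
    data = {
        "nominal_diameter": float(spec.nominal_diameter),
        "n_tines": int(spec.n_tines),
        "deployed_fraction": float(spec.deployed_fraction),
        "wire_radius": float(spec.wire_radius),
        "shaft_length": float(spec.shaft_length),
        "shaft_axis": spec.shaft_axis.tolist(),
        "tip_position": spec.tip_position.tolist(),
        "tine_paths": [p.tolist() for p in spec.tine_paths],
    }
    with open(path, "w") as f:
        yaml.safe_dump(data, f, sort_keys=False)


def load_electrode(path):
    from .geometry import ElectrodeSpec
    with open(path) as f:
        data = yaml.safe_load(f)
    try:
        return ElectrodeSpec(
            nominal_diameter=data["nominal_diameter"],
            n_tines=data["n_tines"],
            shaft_axis=np.asarray(data["shaft_axis"], float),
            tip_position=np.asarray(data["tip_position"], float),
            tine_paths=tuple(np.asarray(p, float) for p in data["tine_paths"]),
            deployed_fraction=data.get("deployed_fraction", 1.0),
            wire_radius=data.get("wire_radius", 0.4),
            shaft_length=data.get("shaft_length", 120.0),
        )
    except KeyError as e:
        raise FormatError(f"electrode config missing key {e}") from None


def save_report(path, report_dict: dict):
    with open(path, "w") as f:
        json.dump(_to_plain(report_dict), f, indent=2)


def save_points_csv(path, points: np.ndarray, header="x_mm,y_mm,z_mm"):
    np.savetxt(path, np.atleast_2d(points), delimiter=",", header=header,
               comments="")
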
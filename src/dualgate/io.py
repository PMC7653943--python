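"""File formats: NIfTI-1 gated volume sets with JSON sidecars.

A gated set is stored as a single 4-D NIfTI file whose fourth axis
enumerates the dual gates, plus a ``<name>.json`` sidecar mapping that axis
to 1-based (respiratory, cardiac) indices and recording dwell fractions and
geometry.  Volumes are written as 32-bit float.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import InputError
from .motion_models import GateScheme
from .phantom_sim import GatedImageSet, VolumeImage

__all__ = ["write_gated_set", "read_gated_set", "write_volume", "read_volume"]


def _affine(voxel_size_mm, origin_mm) -> np.ndarray:
    affine = np.diag([*voxel_size_mm, 1.0])
    affine[:3, 3] = origin_mm
    return affine


def write_gated_set(image_set: GatedImageSet, base_path) -> tuple[Path, Path]:
    """Write a gated set as ``<base>.nii`` + ``<base>.json``; returns paths."""
    base = Path(base_path)
    keys = image_set.gate_keys()
    ref = image_set.volumes[keys[0]]
    data = np.stack(
        [image_set.volumes[k].voxels.astype(np.float32) for k in keys], axis=-1
    )
    img = nib.Nifti1Image(data, _affine(ref.voxel_size_mm, ref.origin_mm))
    nii_path = base.with_suffix(".nii")
    nib.save(img, nii_path)
    sidecar = {
        "scheme": {"n_resp": image_set.scheme.n_resp, "n_card": image_set.scheme.n_card},
        "gate_order": [list(k) for k in keys],
        "gate_fractions": {f"{i},{j}": image_set.gate_fractions[(i, j)] for i, j in keys},
        "voxel_size_mm": list(ref.voxel_size_mm),
        "origin_mm": list(ref.origin_mm),
    }
    json_path = base.with_suffix(".json")
    json_path.write_text(json.dumps(sidecar, indent=2) + "\n")
    return nii_path, json_path


def read_gated_set(base_path) -> GatedImageSet:
    """Read a gated set written by :func:`write_gated_set`."""
    base = Path(base_path)
    sidecar = json.loads(base.with_suffix(".json").read_text())
    img = nib.load(base.with_suffix(".nii"))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise InputError(f"{base}: expected a 4-D gated NIfTI file")
    voxel = tuple(sidecar["voxel_size_mm"])
    origin = tuple(sidecar["origin_mm"])
    keys = [tuple(k) for k in sidecar["gate_order"]]
    if len(keys) != data.shape[3]:
        raise InputError(f"{base}: sidecar gate order does not match the 4th axis")
    volumes = {
        key: VolumeImage(data[..., idx], voxel, origin) for idx, key in enumerate(keys)
    }
    fractions = {
        tuple(int(x) for x in key.split(",")): float(v)
        for key, v in sidecar["gate_fractions"].items()
    }
    scheme = GateScheme(sidecar["scheme"]["n_resp"], sidecar["scheme"]["n_card"])
    return GatedImageSet(scheme=scheme, volumes=volumes, gate_fractions=fractions)


def write_volume(volume: VolumeImage, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(
        volume.voxels.astype(np.float32),
        _affine(volume.voxel_size_mm, volume.origin_mm),
    )
    nib.save(img, path)
    return path


def read_volume(path) -> VolumeImage:
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise InputError(f"{path}: expected a 3-D NIfTI file")
    affine = img.affine
    voxel = tuple(float(affine[k, k]) for k in range(3))
    origin = tuple(float(affine[k, 3]) for k in range(3))
    return VolumeImage(data, voxel, origin)
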
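"""NIfTI volume and YAML/JSON config I/O helpers."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = ["save_nifti", "load_nifti", "load_config", "dump_config"]


def save_nifti(volume: np.ndarray, voxel_size: float, path) -> None:
    """Write a volume as NIfTI-1 with an affine carrying the voxel size."""
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    data = np.asarray(volume)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif data.dtype not in (np.uint8, np.int16, np.int32):
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, float]:
    """Read a NIfTI volume; returns (data, isotropic voxel size in mm)."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise ValueError(f"anisotropic voxels not supported: {zooms}")
    return np.asarray(img.dataobj), float(zooms[0])


def load_config(path) -> dict:
    """Load a YAML or JSON config file into a dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def dump_config(config: dict, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config, indent=2))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=False))
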
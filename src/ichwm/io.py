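"""File formats: NIfTI-1 volumes, FSL bvec/bval gradients, ROI JSON, YAML config.

The interchange format is NIfTI-1 with an axis-aligned, positive-spacing
affine (identity orientation). Rotated or flipped orientations are refused
explicitly rather than silently resampled — the geometry conventions of the
ROI layer (voxel centers at index × spacing) depend on it.

Gradients use the FSL dialect: ``.bval`` one whitespace-separated row of
b-values, ``.bvec`` three rows (x, y, z components), one column per volume.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .dti import DiffusionVolume, GradientScheme, ScalarMap
from .roi import SphericalROI


class UnsupportedOrientationError(ValueError):
    """NIfTI affine is not axis-aligned with positive spacings."""


def _check_affine(affine: np.ndarray, path) -> tuple[float, float, float]:
    rot = np.asarray(affine, dtype=float)[:3, :3]
    diag = np.diag(rot)
    off = rot - np.diag(diag)
    if np.any(np.abs(off) > 1e-4 * max(1.0, np.abs(diag).max())) or np.any(diag <= 0):
        raise UnsupportedOrientationError(
            f"{path}: only identity-orientation NIfTI (axis-aligned affine with "
            f"positive spacings) is supported"
        )
    return tuple(float(d) for d in diag)


def load_nifti_volume(path, expect_ndim: int = 3):
    """Load a NIfTI volume; returns ``(data, voxel_spacing)``.

    Raises for a missing file, a malformed header, a non-identity
    orientation, or an unexpected dimensionality (e.g. 4D where 3D is
    required).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    spacing = _check_affine(img.affine, path)
    data = np.asarray(img.get_fdata())
    if data.ndim != expect_ndim:
        raise ValueError(f"{path}: expected {expect_ndim}D data, found {data.ndim}D")
    return data, spacing


def save_nifti(data: np.ndarray, voxel_spacing, path, dtype=np.float32):
    """Write a volume with a diagonal (identity-orientation) affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(voxel_spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    img.header.set_zooms(tuple(voxel_spacing) + ((1.0,) if np.asarray(data).ndim == 4 else ()))
    nib.save(img, str(path))
    return path


def save_mask(mask: np.ndarray, voxel_spacing, path):
    return save_nifti(np.asarray(mask, dtype=np.uint8), voxel_spacing, path, dtype=np.uint8)


def save_scalar_map(m: ScalarMap, path):
    return save_nifti(m.data, m.voxel_spacing, path, dtype=np.float32)


def load_scalar_map(path, kind: str) -> ScalarMap:
    data, spacing = load_nifti_volume(path, expect_ndim=3)
    return ScalarMap(data, kind, spacing)


def write_fsl_gradients(scheme: GradientScheme, bvec_path, bval_path):
    """Write the FSL-dialect 3×N ``.bvec`` and 1×N ``.bval`` text files."""
    np.savetxt(bval_path, scheme.b_values[None, :], fmt="%.1f")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.8f")


def read_fsl_gradients(bvec_path, bval_path) -> GradientScheme:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    return GradientScheme(bvals, bvecs)


def save_dwi(dwi: DiffusionVolume, prefix) -> dict:
    """Write DWI as ``<prefix>.nii.gz`` + ``<prefix>.bvec/.bval``; returns paths."""
    prefix = Path(prefix)
    paths = {
        "dwi": save_nifti(dwi.data, dwi.voxel_spacing, prefix.with_suffix(".nii.gz")),
        "bvec": prefix.with_suffix(".bvec"),
        "bval": prefix.with_suffix(".bval"),
    }
    write_fsl_gradients(dwi.scheme, paths["bvec"], paths["bval"])
    return paths


def load_dwi(dwi_path, bvec_path, bval_path) -> DiffusionVolume:
    data, spacing = load_nifti_volume(dwi_path, expect_ndim=4)
    scheme = read_fsl_gradients(bvec_path, bval_path)
    return DiffusionVolume(data, scheme, spacing[:3])


def save_roi_json(rois, path):
    """Serialise one or more spherical ROIs to JSON."""
    if isinstance(rois, SphericalROI):
        rois = [rois]
    payload = [{"center_mm": list(r.center_mm), "radius_mm": r.radius_mm, "side": r.side}
               for r in rois]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_roi_json(path) -> list[SphericalROI]:
    payload = json.loads(Path(path).read_text())
    return [SphericalROI(tuple(p["center_mm"]), p["radius_mm"], p["side"]) for p in payload]


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_yaml_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def dump_yaml_config(obj: dict, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=False)
    return path
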
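"""3D image volume container and NIfTI / DICOM I/O.

World coordinates are LPS millimetres (+x left, +y posterior,
+z superior), the DICOM patient frame.  NIfTI stores RAS affines, so
the first two axes are negated on read/write.  ``values`` is indexed
``[i, j, k]`` with world position ``origin + direction @ (spacing * idx)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

_LPS_FLIP = np.diag([-1.0, -1.0, 1.0])


@dataclass
class Volume:
    """A 3D scalar grid with physical spacing and a world frame."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None
    direction: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if not np.all(self.spacing > 0):
            raise ValueError("spacing must be strictly positive")
        self.origin = (np.zeros(3) if self.origin is None
                       else np.asarray(self.origin, dtype=float).reshape(3))
        self.direction = (np.eye(3) if self.direction is None
                          else np.asarray(self.direction, dtype=float).reshape(3, 3))
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return self.origin + (self.direction @ (self.spacing * idx).T).T

    def world_to_index(self, world) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        return (self.direction.T @ (world - self.origin).T).T / self.spacing

    def save_nifti(self, path, *, sidecar: bool = True) -> None:
        """Write the volume as NIfTI (.nii/.nii.gz) with an RAS affine;
        ground-truth/metadata goes to a JSON sidecar next to it."""
        affine = np.eye(4)
        affine[:3, :3] = _LPS_FLIP @ self.direction @ np.diag(self.spacing)
        affine[:3, 3] = _LPS_FLIP @ self.origin
        img = nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), affine)
        nib.save(img, str(path))
        if sidecar and self.meta:
            Path(sidecar_path(path)).write_text(
                json.dumps(_jsonable(self.meta), indent=2))


def sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            name = name[: -len(suf)]
            break
    return p.with_name(name + ".json")


def load_nifti(path) -> Volume:
    """Read a NIfTI volume (and its JSON sidecar, if present) into LPS."""
    img = nib.load(str(path))
    affine = img.affine
    M = _LPS_FLIP @ affine[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    direction = M / spacing
    origin = _LPS_FLIP @ affine[:3, 3]
    meta = {}
    sp = sidecar_path(path)
    if sp.exists():
        meta = json.loads(sp.read_text())
    return Volume(values=np.asanyarray(img.dataobj), spacing=spacing,
                  origin=origin, direction=direction, meta=meta)


def load_dicom_series(folder) -> Volume:
    """Read a DICOM series folder (via SimpleITK) into an LPS volume."""
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(folder))
    if not files:
        raise ValueError(f"no DICOM series found in {folder}")
    reader.SetFileNames(files)
    img = reader.Execute()
    # SimpleITK is LPS already; its array is indexed [z, y, x]
    values = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return Volume(values=values,
                  spacing=np.asarray(img.GetSpacing()),
                  origin=np.asarray(img.GetOrigin()),
                  direction=np.asarray(img.GetDirection()).reshape(3, 3))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
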
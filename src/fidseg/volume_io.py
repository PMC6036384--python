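"""3D MR volume container and I/O with voxel-to-world geometry.

All world coordinates in this package are expressed in the LPS (Left,
Posterior, Superior) patient frame in millimetres, the convention used by
DICOM.  NIfTI files store RAS affines; they are converted on load and save.
Intensities are non-negative integers (the noise-threshold step builds an
integer histogram with bin width 1), so floating-point inputs are rounded
to the nearest integer on load.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "Volume3D",
    "VolumeIOError",
    "load_volume",
    "save_volume",
    "voxel_to_world",
    "world_to_voxel",
]

# RAS <-> LPS: negate the x (Left/Right) and y (Posterior/Anterior) axes.
_RAS2LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


class VolumeIOError(ValueError):
    """Raised for unreadable files or inconsistent DICOM series."""


@dataclass
class Volume3D:
    """A 3D intensity grid plus the affine mapping voxel indices to world mm.

    Parameters
    ----------
    data
        3D array of non-negative integer intensities (arbitrary units).
    affine
        4x4 matrix mapping homogeneous voxel index ``(i, j, k, 1)`` to world
        ``(x, y, z, 1)`` in mm, LPS convention.  Must be invertible.
    meta
        Free-form acquisition metadata (sequence name, slice thickness,
        slice gap, commanded table shift, ...).
    """

    data: np.ndarray
    affine: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("intensities must be integers; round on load")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be >= 0")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing (dx, dy, dz) in mm along the three logical axes.

        For gapped 2D acquisitions dz is the reconstructed inter-slice
        spacing, i.e. slice thickness + gap.
        """
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (dz includes any slice gap)."""
        return float(np.prod(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def voxel_to_world(v: Volume3D, idx: np.ndarray) -> np.ndarray:
    """Map (fractional) voxel indices to world mm (LPS).

    ``idx`` may be a single triple or an (N, 3) array; out-of-grid indices
    are allowed.
    """
    idx = np.asarray(idx, dtype=float)
    return idx @ v.affine[:3, :3].T + v.affine[:3, 3]


def world_to_voxel(v: Volume3D, xyz: np.ndarray) -> np.ndarray:
    """Inverse of :func:`voxel_to_world` (round-trips to ~1e-9 mm)."""
    xyz = np.asarray(xyz, dtype=float)
    inv = np.linalg.inv(v.affine)
    return xyz @ inv[:3, :3].T + inv[:3, 3]


# ---------------------------------------------------------------------------
# Loading


def load_volume(path: str | os.PathLike, format: str | None = None) -> Volume3D:
    """Load a 3D volume from NIfTI, a DICOM series directory, or the
    internal ``.npz`` format.

    The format is inferred from the path when not given.  Floating-point
    intensities are rounded to the nearest integer (recorded in ``meta``);
    NIfTI RAS affines are converted to LPS.
    """
    path = os.fspath(path)
    if format is None:
        if os.path.isdir(path):
            format = "dicom_dir"
        elif path.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif path.endswith(".npz"):
            format = "internal"
        else:
            raise VolumeIOError(f"cannot infer format of {path!r}")
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom_dir":
        return _load_dicom_dir(path)
    if format == "internal":
        return _load_internal(path)
    raise VolumeIOError(f"unknown format {format!r}")


def _round_to_int(data: np.ndarray, meta: dict) -> np.ndarray:
    if not np.issubdtype(data.dtype, np.integer):
        meta["rounded_from_float"] = True
        data = np.rint(data).astype(np.int32)
    else:
        data = data.astype(np.int32, copy=False)
    return np.maximum(data, 0)


def _load_nifti(path: str) -> Volume3D:
    import nibabel as nib

    try:
        img = nib.load(path)
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise VolumeIOError(f"cannot read NIfTI {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeIOError(f"{path!r}: expected 3D data, got shape {data.shape}")
    meta: dict[str, Any] = {"source": path, "format": "nifti"}
    data = _round_to_int(data, meta)
    affine = _RAS2LPS @ img.affine  # nibabel reports RAS
    return Volume3D(data, affine, meta)


def _load_internal(path: str) -> Volume3D:
    with np.load(path, allow_pickle=False) as npz:
        data = npz["data"]
        affine = npz["affine"]
        meta = json.loads(str(npz["meta"])) if "meta" in npz else {}
    return Volume3D(data.astype(np.int32), affine, meta)


def _load_dicom_dir(path: str) -> Volume3D:
    import pydicom

    files = sorted(
        os.path.join(path, f)
        for f in os.listdir(path)
        if not f.startswith(".")
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "ImagePositionPatient") and hasattr(ds, "PixelData"):
            slices.append(ds)
    if len(slices) < 2:
        raise VolumeIOError(f"{path!r}: need at least 2 DICOM slices")

    iop = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    for ds in slices[1:]:
        if not np.allclose(np.asarray(ds.ImageOrientationPatient, float), iop, atol=1e-4):
            raise VolumeIOError(f"{path!r}: mixed slice orientations in series")
    row, col = iop[:3], iop[3:]
    normal = np.cross(row, col)

    # sort slices along the normal and check uniform spacing
    pos = np.array([np.asarray(s.ImagePositionPatient, float) for s in slices])
    order = np.argsort(pos @ normal)
    slices = [slices[i] for i in order]
    pos = pos[order]
    steps = np.diff(pos @ normal)
    if np.ptp(steps) > 1e-3:
        raise VolumeIOError(f"{path!r}: non-uniform inter-slice spacing {steps}")
    dz = float(steps.mean())
    if dz <= 0:
        raise VolumeIOError(f"{path!r}: degenerate slice positions")

    ps = np.asarray(slices[0].PixelSpacing, dtype=float)  # (row, col) mm
    for ds in slices[1:]:
        if not np.allclose(np.asarray(ds.PixelSpacing, float), ps, atol=1e-6):
            raise VolumeIOError(f"{path!r}: mixed pixel spacings in series")

    arrs = [s.pixel_array for s in slices]
    if len({a.shape for a in arrs}) != 1:
        raise VolumeIOError(f"{path!r}: mixed slice shapes")
    # pixel_array is (rows, cols); logical axes (i, j, k) = (col, row, slice)
    data = np.stack([a.T for a in arrs], axis=2)
    meta: dict[str, Any] = {
        "source": path,
        "format": "dicom_dir",
        "slice_spacing_mm": dz,
        "slice_thickness_mm": float(getattr(slices[0], "SliceThickness", dz)),
    }
    data = _round_to_int(data, meta)

    affine = np.eye(4)
    # DICOM: column index advances along `row` direction with PixelSpacing[1],
    # row index along `col` direction with PixelSpacing[0]; already LPS.
    affine[:3, 0] = row * ps[1]
    affine[:3, 1] = col * ps[0]
    affine[:3, 2] = normal * dz
    affine[:3, 3] = pos[0]
    return Volume3D(data, affine, meta)


# ---------------------------------------------------------------------------
# Saving


def save_volume(v: Volume3D, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a volume to NIfTI (``.nii``/``.nii.gz``) or internal ``.npz``."""
    path = os.fspath(path)
    if format is None:
        format = "internal" if path.endswith(".npz") else "nifti"
    if format == "nifti":
        import nibabel as nib

        img = nib.Nifti1Image(v.data.astype(np.int32), _RAS2LPS @ v.affine)
        nib.save(img, path)
    elif format == "internal":
        np.savez_compressed(
            path, data=v.data.astype(np.int32), affine=v.affine,
            meta=np.str_(json.dumps(v.meta, default=str)),
        )
    else:
        raise VolumeIOError(f"unknown format {format!r}")


def save_labeled_mask(labels: np.ndarray, like: Volume3D, path: str | os.PathLike) -> None:
    """Write an integer label mask on the grid of ``like`` as NIfTI."""
    save_volume(Volume3D(labels.astype(np.int32), like.affine, {"kind": "mask"}), path)
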
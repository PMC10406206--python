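"""Volume, mask and displacement-field I/O on axis-aligned grids.

All images live on regular axis-aligned grids described by a voxel
``spacing`` (mm per axis) and an ``origin`` (world position, in mm, of the
*center* of voxel ``(0, 0, 0)``).  World coordinates of voxel ``i`` along
axis ``a`` are ``origin[a] + i * spacing[a]``.  NIfTI files are reoriented
to the closest canonical (RAS) axis order on load so that this convention
holds internally regardless of how the file was stored.

Skull-stripping, bias correction and rigid pre-alignment are assumed done
upstream; this module only moves data onto the cubic working grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ScalarVolume",
    "MultiSequenceVolume",
    "PathologyMask",
    "read_volume",
    "write_volume",
    "read_displacement_field",
    "write_displacement_field",
    "resample_to_cube",
]


@dataclass
class ScalarVolume:
    """A 3D scalar image with grid metadata.

    Parameters
    ----------
    data:
        3D array of intensities (arbitrary units).
    spacing:
        Per-axis voxel size in mm, all components > 0.
    origin:
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3 (the midpoint-quadrature weight)."""
        return float(np.prod(self.spacing))

    def same_grid(self, other: "ScalarVolume | PathologyMask", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class PathologyMask:
    """Binary mask of pathological tissue on the fixed image's grid.

    Voxels with value 1 are excluded from the image distance (the region
    with no counterpart in the other time point, e.g. the resection
    cavity plus tumor tissue).
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {data.shape}")
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be in {{0, 1}}, got {uniq}")
        self.data = data.astype(np.uint8)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    same_grid = ScalarVolume.same_grid


@dataclass
class MultiSequenceVolume:
    """An ordered set of co-registered MRI sequences on one grid."""

    channels: list[ScalarVolume]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.channels) == 0:
            raise ValueError("at least one channel is required")
        ref = self.channels[0]
        for ch in self.channels[1:]:
            if not ref.same_grid(ch):
                raise ValueError("all channels must share shape, spacing and origin")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(len(self.channels))]
        if len(self.labels) != len(self.channels):
            raise ValueError("one label per channel required")

    def __len__(self) -> int:
        return len(self.channels)

    @property
    def grid(self) -> ScalarVolume:
        return self.channels[0]


def _canonical(img: nib.Nifti1Image) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reorder to RAS and extract (data, spacing, origin)."""
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    affine = img.affine
    # After canonical reordering the linear part is (near) diagonal; the
    # column norms are the voxel sizes and the translation is the origin.
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    origin = affine[:3, 3]
    return data, spacing, origin


def read_volume(path: str | Path, kind: str = "intensity") -> ScalarVolume | PathologyMask:
    """Read a 3D NIfTI file as an intensity volume or a binary mask.

    Masks are binarized with threshold > 0.5.  Non-finite voxels in an
    intensity volume are an error.
    """
    if kind not in ("intensity", "mask"):
        raise ValueError(f"kind must be 'intensity' or 'mask', got {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data, spacing, origin = _canonical(img)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    if kind == "mask":
        return PathologyMask((np.asarray(data, dtype=np.float64) > 0.5).astype(np.uint8),
                             spacing, origin)
    return ScalarVolume(np.asarray(data, dtype=np.float64), spacing, origin)


def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def write_volume(v: ScalarVolume | PathologyMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI-1 (float32 / uint8)."""
    if isinstance(v, PathologyMask):
        data = v.data.astype(np.uint8)
    else:
        data = v.data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(v.spacing, v.origin))
    img.header.set_zooms(tuple(v.spacing))
    nib.save(img, str(path))


def write_displacement_field(u, path: str | Path) -> None:
    """Write a displacement field as 5D NIfTI of shape (nx, ny, nz, 1, 3).

    Components are world-mm displacements (the common ANTs-style field
    dialect), stored as float32.
    """
    from .transform import DisplacementField  # local import avoids a cycle

    if not isinstance(u, DisplacementField):
        raise TypeError("expected a DisplacementField")
    if not np.all(np.isfinite(u.u)):
        raise ValueError("displacement field contains non-finite components")
    data = u.u.astype(np.float32)[:, :, :, np.newaxis, :]
    img = nib.Nifti1Image(data, _affine(u.spacing, u.origin))
    img.header.set_intent("vector")
    img.header.set_zooms(tuple(u.spacing) + (1.0, 1.0))
    nib.save(img, str(path))


def read_displacement_field(path: str | Path):
    """Read a 5D (nx, ny, nz, 1, 3) NIfTI displacement field."""
    from .transform import DisplacementField

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 5 and data.shape[3] == 1 and data.shape[4] == 3:
        data = data[:, :, :, 0, :]
    elif not (data.ndim == 4 and data.shape[3] == 3):
        raise ValueError(f"{path}: expected a (nx,ny,nz,1,3) displacement field, "
                         f"got shape {data.shape}")
    affine = img.affine
    spacing = np.abs(np.diag(affine[:3, :3]))
    origin = affine[:3, 3]
    return DisplacementField(np.asarray(data, dtype=np.float64), spacing, origin)


def resample_to_cube(v: ScalarVolume | PathologyMask, n: int,
                     order: str | None = None) -> ScalarVolume | PathologyMask:
    """Resample a volume onto an n^3 grid covering the same world extent.

    The world extent along each axis is the cell-based extent
    ``shape * spacing``; the new spacing is ``extent / n``.  Intensities
    use trilinear interpolation, masks mandatory nearest-neighbour.
    """
    if n < 8:
        raise ValueError(f"cube edge must be >= 8, got {n}")
    is_mask = isinstance(v, PathologyMask)
    if order is None:
        order = "nearest" if is_mask else "linear"
    if order not in ("linear", "nearest"):
        raise ValueError(f"order must be 'linear' or 'nearest', got {order!r}")
    if is_mask and order != "nearest":
        raise ValueError("masks must be resampled with nearest-neighbour")

    shape = np.array(v.shape, dtype=np.float64)
    extent = shape * v.spacing
    new_spacing = extent / n
    # cell-based extent: domain starts at origin - spacing/2
    new_origin = v.origin - v.spacing / 2 + new_spacing / 2
    # voxel coordinates (old frame) of the new voxel centers, per axis
    coords1d = [
        (new_origin[a] + np.arange(n) * new_spacing[a] - v.origin[a]) / v.spacing[a]
        for a in range(3)
    ]
    grid = np.meshgrid(*coords1d, indexing="ij")
    interp_order = 0 if order == "nearest" else 1
    out = ndimage.map_coordinates(
        v.data.astype(np.float64), np.stack(grid), order=interp_order, mode="nearest"
    )
    if is_mask:
        return PathologyMask((out > 0.5).astype(np.uint8), new_spacing, new_origin)
    return ScalarVolume(out, new_spacing, new_origin)
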
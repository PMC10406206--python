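"""Deformations y(x) = x + u(x): warping, pyramid transfer, regularity.

Displacement fields are stored in world millimetres at every resolution
level, so moving a field across levels is pure interpolation — no
magnitude rescaling.  Spatial derivatives use spacing-aware central
differences with one-sided stencils on boundary faces; their adjoints are
provided for building analytic objective gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .volume_io import PathologyMask, ScalarVolume

__all__ = [
    "DisplacementField",
    "warp_image",
    "restrict_volume",
    "restrict_mask",
    "restrict_field",
    "prolong_field",
    "jacobian_determinant",
    "folding_fraction",
    "gradient_axis",
    "gradient_axis_adjoint",
    "laplacian_stencil",
    "laplacian_stencil_adjoint",
    "sample_trilinear",
]


@dataclass
class DisplacementField:
    """Per-voxel displacement u (mm) on a stated grid; y(x) = x + u(x)."""

    u: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.u.ndim != 4 or self.u.shape[3] != 3:
            raise ValueError(f"expected field of shape (nx, ny, nz, 3), got {self.u.shape}")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite components")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.u.shape[:3]  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @classmethod
    def zeros_like_grid(cls, shape: Iterable[int], spacing, origin) -> "DisplacementField":
        return cls(np.zeros(tuple(shape) + (3,)), spacing, origin)

    def same_grid(self, other, tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


# ---------------------------------------------------------------------------
# trilinear sampling with its exact coordinate derivative
# ---------------------------------------------------------------------------

def sample_trilinear(data: np.ndarray, vox: np.ndarray, gradient: bool = False):
    """Trilinear interpolation of ``data`` at voxel coordinates ``vox``.

    ``vox`` has shape (..., 3).  Out-of-domain coordinates clamp to the
    edge (constant extension), where the coordinate derivative is zero.
    Returns the sampled values, and with ``gradient=True`` also the exact
    derivative of the interpolant w.r.t. each voxel coordinate,
    shape (..., 3).
    """
    nx, ny, nz = data.shape
    flat = data.ravel()

    cx = np.clip(vox[..., 0], 0.0, nx - 1.0)
    cy = np.clip(vox[..., 1], 0.0, ny - 1.0)
    cz = np.clip(vox[..., 2], 0.0, nz - 1.0)
    ix = np.minimum(cx.astype(np.int64), nx - 2) if nx > 1 else np.zeros_like(cx, np.int64)
    iy = np.minimum(cy.astype(np.int64), ny - 2) if ny > 1 else np.zeros_like(cy, np.int64)
    iz = np.minimum(cz.astype(np.int64), nz - 2) if nz > 1 else np.zeros_like(cz, np.int64)
    fx = cx - ix
    fy = cy - iy
    fz = cz - iz

    base = (ix * ny + iy) * nz + iz
    syz = ny * nz
    c000 = flat[base]
    c001 = flat[base + 1]
    c010 = flat[base + nz]
    c011 = flat[base + nz + 1]
    c100 = flat[base + syz]
    c101 = flat[base + syz + 1]
    c110 = flat[base + syz + nz]
    c111 = flat[base + syz + nz + 1]

    # collapse z, then y, then x (two-weight form: exact at f = 0 and f = 1)
    gz = 1.0 - fz
    gy = 1.0 - fy
    c00 = c000 * gz + c001 * fz
    c01 = c010 * gz + c011 * fz
    c10 = c100 * gz + c101 * fz
    c11 = c110 * gz + c111 * fz
    c0 = c00 * gy + c01 * fy
    c1 = c10 * gy + c11 * fy
    val = c0 * (1.0 - fx) + c1 * fx
    if not gradient:
        return val

    dx = c1 - c0
    dy = (c01 - c00) * (1.0 - fx) + (c11 - c10) * fx
    dz0 = (c001 - c000) * gy + (c011 - c010) * fy
    dz1 = (c101 - c100) * gy + (c111 - c110) * fy
    dz = dz0 * (1.0 - fx) + dz1 * fx

    # clamped samples are constant along the clamped axis
    dx = np.where((vox[..., 0] < 0) | (vox[..., 0] > nx - 1), 0.0, dx)
    dy = np.where((vox[..., 1] < 0) | (vox[..., 1] > ny - 1), 0.0, dy)
    dz = np.where((vox[..., 2] < 0) | (vox[..., 2] > nz - 1), 0.0, dz)
    return val, np.stack([dx, dy, dz], axis=-1)


def _world_coords(shape, spacing, origin) -> list[np.ndarray]:
    """Per-axis 1D world coordinates of voxel centers."""
    return [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]


def warp_points(t: ScalarVolume, points_world: np.ndarray, gradient: bool = False):
    """Sample ``t`` at world points (..., 3); optionally also d/dworld (mm^-1)."""
    vox = (points_world - t.origin) / t.spacing
    out = sample_trilinear(t.data, vox, gradient=gradient)
    if not gradient:
        return out
    val, dvox = out
    return val, dvox / t.spacing


def warp_image(t: ScalarVolume, u: DisplacementField, gradient: bool = False):
    """Evaluate T(y(x)) = T(x + u(x)) on the fixed grid carried by ``u``.

    With ``gradient=True`` additionally returns the exact derivative of
    the warped value w.r.t. the displacement components (i.e. the spatial
    derivative of the interpolant of T at y(x), in mm^-1), shape
    (nx, ny, nz, 3).
    """
    if t.same_grid(u):
        # same grid: voxel coordinates are i + u/spacing, exactly
        idx = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in u.shape],
                                   indexing="ij"), axis=-1)
        vox = idx + u.u / t.spacing
        out = sample_trilinear(t.data, vox, gradient=gradient)
        if gradient:
            val, dvox = out
            return ScalarVolume(val, u.spacing, u.origin), dvox / t.spacing
        return ScalarVolume(out, u.spacing, u.origin)
    xs = _world_coords(u.shape, u.spacing, u.origin)
    X = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1)
    out = warp_points(t, X + u.u, gradient=gradient)
    if gradient:
        val, dval = out
        return ScalarVolume(val, u.spacing, u.origin), dval
    return ScalarVolume(out, u.spacing, u.origin)


# ---------------------------------------------------------------------------
# resolution transfer
# ---------------------------------------------------------------------------

def restrict_volume(v: ScalarVolume) -> ScalarVolume:
    """Halve each edge by 2x2x2 average pooling; spacing doubles."""
    nx, ny, nz = v.shape
    if min(nx, ny, nz) < 2 or nx % 2 or ny % 2 or nz % 2:
        raise ValueError(f"restriction needs even edges >= 2, got shape {v.shape}")
    d = v.data.reshape(nx // 2, 2, ny // 2, 2, nz // 2, 2).mean(axis=(1, 3, 5))
    # new voxel centers sit midway between each 2x2x2 block's corners
    return ScalarVolume(d, v.spacing * 2, v.origin + v.spacing / 2)


def restrict_field(u: DisplacementField) -> DisplacementField:
    """Average-pool a displacement field to the next coarser level (mm kept)."""
    nx, ny, nz = u.shape
    if min(nx, ny, nz) < 2 or nx % 2 or ny % 2 or nz % 2:
        raise ValueError(f"restriction needs even edges >= 2, got shape {u.shape}")
    d = u.u.reshape(nx // 2, 2, ny // 2, 2, nz // 2, 2, 3).mean(axis=(1, 3, 5))
    return DisplacementField(d, u.spacing * 2, u.origin + u.spacing / 2)


def restrict_mask(m: PathologyMask) -> PathologyMask:
    """Average-pool then re-binarize at >= 0.5 (preserves pathology volume)."""
    nx, ny, nz = m.shape
    if min(nx, ny, nz) < 2 or nx % 2 or ny % 2 or nz % 2:
        raise ValueError(f"restriction needs even edges >= 2, got shape {m.shape}")
    d = m.data.astype(np.float64).reshape(nx // 2, 2, ny // 2, 2, nz // 2, 2).mean(axis=(1, 3, 5))
    return PathologyMask((d >= 0.5).astype(np.uint8), m.spacing * 2, m.origin + m.spacing / 2)


def prolong_field(u: DisplacementField, shape, spacing, origin) -> DisplacementField:
    """Trilinearly resample a displacement field onto a target grid.

    Components are world mm, so values transfer without rescaling.  The
    target grid must cover the same world extent (cell-based) as the
    source grid.
    """
    shape = tuple(int(s) for s in shape)
    spacing = np.asarray(spacing, dtype=np.float64).reshape(3)
    origin = np.asarray(origin, dtype=np.float64).reshape(3)
    lo_s = u.origin - u.spacing / 2
    hi_s = lo_s + np.array(u.shape) * u.spacing
    lo_t = origin - spacing / 2
    hi_t = lo_t + np.array(shape) * spacing
    tol = 0.25 * np.maximum(u.spacing, spacing)
    if np.any(np.abs(lo_s - lo_t) > tol) or np.any(np.abs(hi_s - hi_t) > tol):
        raise ValueError("target grid does not cover the source field's world extent")
    xs = _world_coords(shape, spacing, origin)
    X = np.stack(np.meshgrid(*xs, indexing="ij"), axis=-1)
    vox = (X - u.origin) / u.spacing
    out = np.empty(shape + (3,))
    for k in range(3):
        out[..., k] = sample_trilinear(u.u[..., k], vox)
    return DisplacementField(out, spacing, origin)


# ---------------------------------------------------------------------------
# difference stencils and their adjoints
# ---------------------------------------------------------------------------

def gradient_axis(f: np.ndarray, axis: int, h: float) -> np.ndarray:
    """Central-difference derivative along ``axis`` (one-sided at faces)."""
    return np.gradient(f, h, axis=axis)


def gradient_axis_adjoint(w: np.ndarray, axis: int, h: float) -> np.ndarray:
    """Adjoint (transpose) of :func:`gradient_axis` as a linear operator."""
    wm = np.moveaxis(w, axis, 0)
    out = np.zeros_like(wm)
    out[2:] += wm[1:-1] / (2.0 * h)
    out[:-2] -= wm[1:-1] / (2.0 * h)
    out[1] += wm[0] / h
    out[0] -= wm[0] / h
    out[-1] += wm[-1] / h
    out[-2] -= wm[-1] / h
    return np.moveaxis(out, 0, axis)


def laplacian_stencil(f: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """7-point Laplacian, evaluated where the full central stencil fits.

    On boundary faces the second-derivative contribution along the
    normal axis is zero (linear-extrapolation ghost values), so affine
    fields have identically zero Laplacian — the discrete analogue of
    their harmonicity, which keeps them free under the curvature
    penalty.
    """
    out = np.zeros_like(f)
    for axis in range(3):
        h2 = float(spacing[axis]) ** 2
        fm = np.moveaxis(f, axis, 0)
        om = np.moveaxis(out, axis, 0)
        om[1:-1] += (fm[2:] - 2.0 * fm[1:-1] + fm[:-2]) / h2
    return out


def laplacian_stencil_adjoint(w: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Adjoint (transpose) of :func:`laplacian_stencil`."""
    out = np.zeros_like(w)
    for axis in range(3):
        h2 = float(spacing[axis]) ** 2
        wm = np.moveaxis(w, axis, 0)
        om = np.moveaxis(out, axis, 0)
        om[2:] += wm[1:-1] / h2
        om[1:-1] -= 2.0 * wm[1:-1] / h2
        om[:-2] += wm[1:-1] / h2
    return out


# ---------------------------------------------------------------------------
# field regularity
# ---------------------------------------------------------------------------

def _jacobian_entries(u: DisplacementField) -> list[list[np.ndarray]]:
    """J[k][l] = d y_k / d x_l = delta_kl + d u_k / d x_l on the grid."""
    J = [[None] * 3 for _ in range(3)]
    for k in range(3):
        for l in range(3):
            d = gradient_axis(u.u[..., k], l, float(u.spacing[l]))
            if k == l:
                d = d + 1.0
            J[k][l] = d
    return J


def _det3(J) -> np.ndarray:
    return (
        J[0][0] * (J[1][1] * J[2][2] - J[1][2] * J[2][1])
        - J[0][1] * (J[1][0] * J[2][2] - J[1][2] * J[2][0])
        + J[0][2] * (J[1][0] * J[2][1] - J[1][1] * J[2][0])
    )


def jacobian_determinant(u: DisplacementField) -> ScalarVolume:
    """Voxelwise det(∇y) with ∇y = I + ∇u from the difference stencils."""
    if min(u.shape) < 3:
        raise ValueError(f"need edge lengths >= 3, got {u.shape}")
    det = _det3(_jacobian_entries(u))
    return ScalarVolume(det, u.spacing, u.origin)


def folding_fraction(u: DisplacementField) -> float:
    """Fraction of voxels where the deformation folds (det(∇y) <= 0)."""
    det = jacobian_determinant(u).data
    return float(np.mean(det <= 0.0))
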
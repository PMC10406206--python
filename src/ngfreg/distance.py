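"""Masked normalized-gradient-fields (NGF) image distance.

NGF scores how well the *directions* of intensity change agree between
the reference R (post-operative) and the warped template T∘y
(pre-operative), which makes it robust to the inconsistent intensity
profiles of longitudinal MRI.  Per voxel the integrand is

    1/2 * (1 - rho^2),   rho = (<∇R, ∇T> + eps_R * eps_T)
                               / (||∇T||_{eps_T} * ||∇R||_{eps_R})

with the regularized norm ||v||_eps = sqrt(v.v + eps^2).  The edge
parameters eps suppress gradients at or below the noise level.  Voxels
inside the pathology mask Σ (tissue with no counterpart across time
points) contribute exactly zero, restricting the integral to Ω \\ Σ.

The discretization is the midpoint rule (voxel volume x sum over
voxels); the gradient with respect to the displacement is exact for this
discretization — chain rule through the difference stencils and through
the trilinear interpolant of the warp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transform import (
    DisplacementField,
    gradient_axis,
    gradient_axis_adjoint,
    sample_trilinear,
)
from .volume_io import MultiSequenceVolume, PathologyMask, ScalarVolume

__all__ = [
    "EdgeParameters",
    "spatial_gradient",
    "ngf_distance",
    "ngf_distance_gradient",
    "multichannel_distance",
    "MultichannelNGF",
    "estimate_edge_parameter",
]

# fallback edge parameter for degenerate (constant) images
_EPS_FALLBACK = 1e-3


@dataclass(frozen=True)
class EdgeParameters:
    """NGF edge parameters (intensity-gradient units), both > 0."""

    eps_r: float
    eps_t: float

    def __post_init__(self) -> None:
        if self.eps_r <= 0 or self.eps_t <= 0:
            raise ValueError(f"edge parameters must be positive, got {self}")


def spatial_gradient(v: ScalarVolume) -> np.ndarray:
    """Spacing-aware gradient, shape (nx, ny, nz, 3) in intensity/mm."""
    if min(v.shape) < 3:
        raise ValueError(f"need edge lengths >= 3, got {v.shape}")
    return np.stack(
        [gradient_axis(v.data, a, float(v.spacing[a])) for a in range(3)], axis=-1
    )


def estimate_edge_parameter(v: ScalarVolume, eta: float = 0.1) -> float:
    """eta times the mean gradient magnitude of the image.

    A practical automatic choice: gradients comparable to the mean are
    treated as edges, much weaker ones as noise.  Falls back to a fixed
    small constant for constant images.
    """
    if not 0 < eta <= 1:
        raise ValueError(f"eta must be in (0, 1], got {eta}")
    g = spatial_gradient(v)
    mean_mag = float(np.mean(np.sqrt(np.sum(g * g, axis=-1))))
    if mean_mag == 0.0:
        return _EPS_FALLBACK
    return eta * mean_mag


def _check_grids(r, other, mask) -> None:
    if not r.same_grid(other):
        raise ValueError("reference and template grids differ")
    if mask is not None and not r.same_grid(mask):
        raise ValueError("mask grid differs from the reference grid")


class _NGFChannel:
    """One channel's precomputed reference-side quantities."""

    __slots__ = ("gr", "nr", "t_data", "t_spacing", "t_origin", "eps")

    def __init__(self, r: ScalarVolume, t: ScalarVolume, eps: EdgeParameters):
        self.gr = spatial_gradient(r)
        self.nr = np.sqrt(np.sum(self.gr * self.gr, axis=-1) + eps.eps_r**2)
        self.t_data = t.data
        self.t_spacing = t.spacing
        self.t_origin = t.origin
        self.eps = eps


class MultichannelNGF:
    """Masked multi-channel NGF distance with exact displacement gradient.

    Precomputes everything that does not depend on the displacement
    (reference gradients and norms, mask weights, fixed-grid world
    coordinates) so repeated evaluations inside the optimizer only pay
    for the warp and the template-side algebra.
    """

    def __init__(self, r: MultiSequenceVolume, t: MultiSequenceVolume,
                 mask: PathologyMask | None, eps: list[EdgeParameters]):
        if len(r) != len(t):
            raise ValueError(f"channel count mismatch: {len(r)} vs {len(t)}")
        if len(eps) != len(r):
            raise ValueError("one EdgeParameters per channel required")
        for rc, tc in zip(r.channels, t.channels):
            _check_grids(rc, tc, mask)
        grid = r.grid
        self.shape = grid.shape
        self.spacing = grid.spacing
        self.h = grid.voxel_volume
        self.keep = None if mask is None else (1.0 - mask.data.astype(np.float64))
        # templates share the reference grid, so voxel coordinates of the
        # warp are exactly i + u/spacing
        self.idx = np.stack(
            np.meshgrid(*[np.arange(s, dtype=float) for s in grid.shape],
                        indexing="ij"), axis=-1)
        self.channels = [_NGFChannel(rc, tc, ec)
                         for rc, tc, ec in zip(r.channels, t.channels, eps)]

    def __call__(self, u_array: np.ndarray, gradient: bool = True):
        # all template channels share one grid: warp coordinates once
        ch0 = self.channels[0]
        vox = self.idx + u_array / ch0.t_spacing
        total = 0.0
        grad = np.zeros(self.shape + (3,)) if gradient else None
        for ch in self.channels:
            out = sample_trilinear(ch.t_data, vox, gradient=gradient)
            tw, dT = out if gradient else (out, None)
            gt = np.stack([gradient_axis(tw, a, float(self.spacing[a]))
                           for a in range(3)], axis=-1)
            nt = np.sqrt(np.sum(gt * gt, axis=-1) + ch.eps.eps_t**2)
            a_ = np.sum(ch.gr * gt, axis=-1) + ch.eps.eps_r * ch.eps.eps_t
            rho = a_ / (ch.nr * nt)
            integrand = 0.5 * (1.0 - rho * rho)
            if self.keep is not None:
                integrand = integrand * self.keep
            total += self.h * float(np.sum(integrand))
            if not gradient:
                continue
            # dD/dgt = h * keep * (-rho) * (gr/(nr nt) - a gt/(nr nt^3))
            coef = self.h * (-rho) / (ch.nr * nt)
            if self.keep is not None:
                coef = coef * self.keep
            w = coef[..., None] * (ch.gr - (a_ / (nt * nt))[..., None] * gt)
            s = gradient_axis_adjoint(w[..., 0], 0, float(self.spacing[0]))
            s += gradient_axis_adjoint(w[..., 1], 1, float(self.spacing[1]))
            s += gradient_axis_adjoint(w[..., 2], 2, float(self.spacing[2]))
            # chain through the warp: dTw/du_k is the interpolant derivative
            grad += s[..., None] * (dT / ch.t_spacing)
        return (total, grad) if gradient else total


def ngf_distance(r: ScalarVolume, t_warped: ScalarVolume,
                 mask: PathologyMask | None, eps: EdgeParameters) -> float:
    """Masked NGF distance between the reference and an already-warped template."""
    _check_grids(r, t_warped, mask)
    gr = spatial_gradient(r)
    gt = spatial_gradient(t_warped)
    nr = np.sqrt(np.sum(gr * gr, axis=-1) + eps.eps_r**2)
    nt = np.sqrt(np.sum(gt * gt, axis=-1) + eps.eps_t**2)
    a = np.sum(gr * gt, axis=-1) + eps.eps_r * eps.eps_t
    rho = a / (nr * nt)
    integrand = 0.5 * (1.0 - rho * rho)
    if mask is not None:
        integrand = integrand * (1.0 - mask.data.astype(np.float64))
    return r.voxel_volume * float(np.sum(integrand))


def ngf_distance_gradient(r: ScalarVolume, t_original: ScalarVolume,
                          u: DisplacementField, mask: PathologyMask | None,
                          eps: EdgeParameters):
    """NGF distance at y = id + u and its exact gradient w.r.t. u.

    Returns ``(value, grad)`` with ``grad`` of shape (nx, ny, nz, 3) —
    the derivative of the discretized distance with respect to each
    displacement component at each fixed-grid voxel.
    """
    if not r.same_grid(u):
        raise ValueError("displacement field grid differs from the reference grid")
    rm = MultiSequenceVolume([r])
    tm = MultiSequenceVolume([t_original])
    return MultichannelNGF(rm, tm, mask, [eps])(u.u)


def multichannel_distance(r: MultiSequenceVolume, t: MultiSequenceVolume,
                          u: DisplacementField, mask: PathologyMask | None,
                          eps: list[EdgeParameters]):
    """Equal-weight sum of per-channel masked NGF distances and gradients."""
    return MultichannelNGF(r, t, mask, eps)(u.u)
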
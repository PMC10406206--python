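"""Curvature regularization and volume-change (folding) control.

The curvature energy penalizes the squared Laplacian of each
displacement component, favoring smooth low-bending deformations;
affine maps have zero energy.  The volume-change term applies the
barrier psi(t) = (t-1)^2 / t to the Jacobian determinant of y, which is
zero at local volume preservation and infinite at folding (t <= 0) —
the line search treats the infinite value as "reject this step".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transform import (
    DisplacementField,
    _det3,
    _jacobian_entries,
    gradient_axis_adjoint,
    laplacian_stencil,
    laplacian_stencil_adjoint,
)

__all__ = [
    "RegularizerWeights",
    "curvature_energy",
    "psi",
    "psi_prime",
    "volume_control_energy",
]


@dataclass
class RegularizerWeights:
    """Weights of the regularization terms of the objective.

    alpha scales the curvature energy, gamma the volume-change control.
    Volume control is off by default for the iterative solver; the flag
    turns it on (gamma then multiplies the barrier term).
    """

    alpha: float = 0.1
    gamma: float = 0.01
    volume_control_enabled: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.gamma < 0:
            raise ValueError("regularizer weights must be nonnegative")


def curvature_energy(u: DisplacementField):
    """Midpoint-rule curvature energy and its exact gradient.

    E = h * sum_voxels sum_k (Lap u_k)^2 with the 7-point Laplacian
    (zero contribution on boundary faces, so affine fields are exactly
    energy-free); the gradient is 2 h Lap^T(Lap u_k) per component.
    """
    if min(u.shape) < 3:
        raise ValueError(f"need edge lengths >= 3, got {u.shape}")
    h = u.voxel_volume
    energy = 0.0
    grad = np.empty_like(u.u)
    for k in range(3):
        lap = laplacian_stencil(u.u[..., k], u.spacing)
        energy += float(np.sum(lap * lap))
        grad[..., k] = 2.0 * h * laplacian_stencil_adjoint(lap, u.spacing)
    return h * energy, grad


def psi(t):
    """Volume-change penalty: (t-1)^2/t for t > 0, infinity for t <= 0."""
    t = np.asarray(t, dtype=np.float64)
    out = np.full_like(t, np.inf)
    pos = t > 0
    tp = t[pos]
    out[pos] = (tp - 1.0) ** 2 / tp
    if out.ndim == 0:
        return float(out)
    return out


def psi_prime(t):
    """d psi / d t = 1 - 1/t^2 on t > 0."""
    t = np.asarray(t, dtype=np.float64)
    return 1.0 - 1.0 / (t * t)


def _cofactors(J):
    """C[k][l] = d det(J) / d J[k][l] for a 3x3 field of matrices."""
    C = [[None] * 3 for _ in range(3)]
    C[0][0] = J[1][1] * J[2][2] - J[1][2] * J[2][1]
    C[0][1] = J[1][2] * J[2][0] - J[1][0] * J[2][2]
    C[0][2] = J[1][0] * J[2][1] - J[1][1] * J[2][0]
    C[1][0] = J[0][2] * J[2][1] - J[0][1] * J[2][2]
    C[1][1] = J[0][0] * J[2][2] - J[0][2] * J[2][0]
    C[1][2] = J[0][1] * J[2][0] - J[0][0] * J[2][1]
    C[2][0] = J[0][1] * J[1][2] - J[0][2] * J[1][1]
    C[2][1] = J[0][2] * J[1][0] - J[0][0] * J[1][2]
    C[2][2] = J[0][0] * J[1][1] - J[0][1] * J[1][0]
    return C


def volume_control_energy(u: DisplacementField):
    """Midpoint-rule volume-change energy and its exact gradient.

    Returns ``(inf, None)`` if any voxel folds (det <= 0); the optimizer
    must then reject the step.  Otherwise the gradient is assembled via
    the cofactor (adjugate) matrix of ∇y pulled back through the
    difference-stencil adjoints.
    """
    if min(u.shape) < 3:
        raise ValueError(f"need edge lengths >= 3, got {u.shape}")
    J = _jacobian_entries(u)
    det = _det3(J)
    if np.any(det <= 0.0):
        return np.inf, None
    h = u.voxel_volume
    energy = h * float(np.sum(psi(det)))
    dpsi = h * psi_prime(det)
    C = _cofactors(J)
    grad = np.zeros_like(u.u)
    for k in range(3):
        for l in range(3):
            grad[..., k] += gradient_axis_adjoint(dpsi * C[k][l], l, float(u.spacing[l]))
    return energy, grad
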
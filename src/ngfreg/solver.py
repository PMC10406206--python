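"""Variational registration: objective assembly, l-BFGS, multi-level loop.

The objective is J(u) = D(R, T(y)) + alpha * curvature(u)
(+ gamma * volume control when enabled), minimized per level with a
limited-memory BFGS (memory 5, Armijo backtracking).  Registration runs
coarse-to-fine on an L-level pyramid built by 2x average-pooling
restriction; each level's field, prolonged to the next finer grid, warps
the moving image there and an additive correction is estimated.  The run
is fully deterministic: zero initial field, no randomness anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .distance import (
    EdgeParameters,
    MultichannelNGF,
    estimate_edge_parameter,
    multichannel_distance,
)
from .regularizers import RegularizerWeights, curvature_energy, volume_control_energy
from .transform import DisplacementField, prolong_field, restrict_mask, restrict_volume, warp_image
from .volume_io import MultiSequenceVolume, PathologyMask, ScalarVolume, resample_to_cube

__all__ = [
    "StoppingCriteria",
    "RegistrationConfig",
    "RegistrationResult",
    "LevelHistory",
    "objective",
    "lbfgs_minimize",
    "register",
]

log = logging.getLogger("ngfreg")


@dataclass
class StoppingCriteria:
    """Per-level termination thresholds for the quasi-Newton iteration."""

    min_progress: float = 0.001
    min_gradient: float = 0.001
    min_relative_gradient: float = 0.001
    min_step_length: float = 0.001
    max_iterations: int = 100

    def __post_init__(self) -> None:
        for name in ("min_progress", "min_gradient", "min_relative_gradient",
                     "min_step_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class RegistrationConfig:
    """Everything the solver needs besides the images themselves.

    eps_r / eps_t, when None, are estimated automatically per channel and
    per level as eps_eta times the mean gradient magnitude.
    """

    weights: RegularizerWeights = field(default_factory=RegularizerWeights)
    levels: int = 3
    working_size: int = 160
    eps_r: float | None = None
    eps_t: float | None = None
    eps_eta: float = 0.1
    stopping: StoppingCriteria = field(default_factory=StoppingCriteria)
    mask_distance: bool = True

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.working_size % (2 ** (self.levels - 1)):
            raise ValueError(
                f"working size {self.working_size} not divisible by 2^(levels-1)"
            )


@dataclass
class LevelHistory:
    level: int
    shape: tuple[int, int, int]
    iterations: int
    objective_values: list[float]
    gradient_norms: list[float]
    step_lengths: list[float]
    reason: str


@dataclass
class RegistrationResult:
    field: DisplacementField
    levels: list[LevelHistory]
    final_components: dict[str, float]


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def objective(u: DisplacementField, fixed: MultiSequenceVolume,
              moving: MultiSequenceVolume, mask: PathologyMask | None,
              config: RegistrationConfig,
              eps: list[EdgeParameters] | None = None):
    """J(u) = D + alpha * curvature (+ gamma * volume control) and its gradient."""
    if eps is None:
        eps = resolve_edge_parameters(fixed, moving, config)
    if not config.mask_distance:
        mask = None
    d, grad = multichannel_distance(fixed, moving, u, mask, eps)
    w = config.weights
    if w.alpha > 0:
        ce, cg = curvature_energy(u)
        d += w.alpha * ce
        grad = grad + w.alpha * cg
    if w.volume_control_enabled and w.gamma > 0:
        ve, vg = volume_control_energy(u)
        if not np.isfinite(ve):
            return np.inf, None
        d += w.gamma * ve
        grad = grad + w.gamma * vg
    return d, grad


def resolve_edge_parameters(fixed: MultiSequenceVolume, moving: MultiSequenceVolume,
                            config: RegistrationConfig) -> list[EdgeParameters]:
    eps = []
    for rc, tc in zip(fixed.channels, moving.channels):
        er = config.eps_r if config.eps_r is not None else estimate_edge_parameter(rc, config.eps_eta)
        et = config.eps_t if config.eps_t is not None else estimate_edge_parameter(tc, config.eps_eta)
        eps.append(EdgeParameters(er, et))
    return eps


# ---------------------------------------------------------------------------
# l-BFGS with Armijo backtracking
# ---------------------------------------------------------------------------

_ARMIJO_SLOPE = 1e-4
_BACKTRACK = 0.5
_MIN_TRIAL = 1e-20


def lbfgs_minimize(fun: Callable[[np.ndarray], tuple[float, np.ndarray | None]],
                   x0: np.ndarray, stopping: StoppingCriteria,
                   memory: int = 5):
    """Limited-memory BFGS with backtracking line search.

    ``fun(x)`` returns ``(value, gradient)``; an infinite value (the
    volume-control folding sentinel) makes the line search reject the
    trial step.  Terminates on the first satisfied stopping criterion;
    accepted iterates have non-increasing objective values.

    Returns ``(x_best, history)`` where history is a dict with the
    objective trace, gradient norms, step lengths, iteration count and
    the termination reason.
    """
    x = np.array(x0, dtype=np.float64, copy=True)
    f, g = fun(x)
    if not np.isfinite(f):
        raise ValueError("objective is not finite at the starting point")
    g = np.asarray(g, dtype=np.float64)
    g0_norm = float(np.linalg.norm(g))
    history = {
        "objective_values": [float(f)],
        "gradient_norms": [g0_norm],
        "step_lengths": [],
        "iterations": 0,
        "reason": "",
    }
    if g0_norm < stopping.min_gradient:
        history["reason"] = "min_gradient"
        return x, history

    s_list: list[np.ndarray] = []
    y_list: list[np.ndarray] = []
    rho_list: list[float] = []

    def direction(grad: np.ndarray) -> np.ndarray:
        q = grad.copy()
        alphas = []
        for s, y, rho in zip(reversed(s_list), reversed(y_list), reversed(rho_list)):
            a = rho * np.dot(s, q)
            alphas.append(a)
            q -= a * y
        if s_list:
            gamma = np.dot(s_list[-1], y_list[-1]) / np.dot(y_list[-1], y_list[-1])
            q *= gamma
        for (s, y, rho), a in zip(zip(s_list, y_list, rho_list), reversed(alphas)):
            b = rho * np.dot(y, q)
            q += (a - b) * s
        return -q

    for it in range(1, stopping.max_iterations + 1):
        d = direction(g)
        slope = float(np.dot(g, d))
        if slope >= 0:  # not a descent direction; fall back to steepest descent
            d = -g
            slope = -float(np.dot(g, g))
        # first step without curvature information: conservative scaling
        t = 1.0 if s_list else min(1.0, 1.0 / max(1.0, float(np.linalg.norm(g))))
        accepted = False
        while t >= _MIN_TRIAL:
            f_new, g_new = fun(x + t * d)
            if np.isfinite(f_new) and f_new <= f + _ARMIJO_SLOPE * t * slope:
                accepted = True
                break
            t *= _BACKTRACK
        if not accepted:
            history["reason"] = "min_step_length"
            return x, history

        s = t * d
        y = np.asarray(g_new) - g
        sy = float(np.dot(s, y))
        if sy > 1e-10 * float(np.linalg.norm(s)) * float(np.linalg.norm(y)):
            s_list.append(s)
            y_list.append(y)
            rho_list.append(1.0 / sy)
            if len(s_list) > memory:
                s_list.pop(0)
                y_list.pop(0)
                rho_list.pop(0)

        progress = f - f_new
        step_len = float(np.linalg.norm(s))
        x = x + s
        f, g = float(f_new), np.asarray(g_new, dtype=np.float64)
        gnorm = float(np.linalg.norm(g))
        history["objective_values"].append(f)
        history["gradient_norms"].append(gnorm)
        history["step_lengths"].append(step_len)
        history["iterations"] = it
        log.debug("iter %3d: objective %.6g  |g| %.4g  step %.4g", it, f, gnorm,
                  step_len)

        if progress < stopping.min_progress:
            history["reason"] = "min_progress"
            return x, history
        if gnorm < stopping.min_gradient:
            history["reason"] = "min_gradient"
            return x, history
        if gnorm / g0_norm < stopping.min_relative_gradient:
            history["reason"] = "min_relative_gradient"
            return x, history
        if step_len < stopping.min_step_length:
            history["reason"] = "min_step_length"
            return x, history

    history["reason"] = "max_iterations"
    return x, history


# ---------------------------------------------------------------------------
# multi-level registration
# ---------------------------------------------------------------------------

def _to_working_grid(vol: MultiSequenceVolume, n: int) -> MultiSequenceVolume:
    if vol.grid.shape == (n, n, n):
        return vol
    return MultiSequenceVolume([resample_to_cube(c, n) for c in vol.channels],
                               list(vol.labels))


def register(fixed: MultiSequenceVolume, moving: MultiSequenceVolume,
             mask: PathologyMask | None, config: RegistrationConfig) -> RegistrationResult:
    """Multi-level masked NGF + curvature registration of moving onto fixed.

    Returns the displacement field on the *input* fixed grid (prolonged
    back from the working cube), the per-level optimization histories and
    the final objective components.
    """
    if len(fixed) != len(moving):
        raise ValueError(f"channel count mismatch: {len(fixed)} vs {len(moving)}")
    if mask is not None and not fixed.grid.same_grid(mask):
        raise ValueError("mask must live on the fixed image's grid")
    for c in fixed.channels:
        if float(np.ptp(c.data)) == 0.0:
            raise ValueError("fixed image is constant; registration is undefined")

    n = config.working_size
    fixed_w = _to_working_grid(fixed, n)
    moving_w = _to_working_grid(moving, n)
    mask_w: PathologyMask | None = None
    if mask is not None and config.mask_distance:
        mask_w = mask if mask.shape == (n, n, n) else resample_to_cube(mask, n)

    # pyramid: index 0 = finest (working grid), L-1 = coarsest
    fixed_pyr = [fixed_w]
    moving_pyr = [moving_w]
    mask_pyr: list[PathologyMask | None] = [mask_w]
    for _ in range(config.levels - 1):
        fixed_pyr.append(MultiSequenceVolume(
            [restrict_volume(c) for c in fixed_pyr[-1].channels], list(fixed_w.labels)))
        moving_pyr.append(MultiSequenceVolume(
            [restrict_volume(c) for c in moving_pyr[-1].channels], list(moving_w.labels)))
        mask_pyr.append(restrict_mask(mask_pyr[-1]) if mask_pyr[-1] is not None else None)

    histories: list[LevelHistory] = []
    u: DisplacementField | None = None
    for level in range(config.levels - 1, -1, -1):
        f_l, m_l, s_l = fixed_pyr[level], moving_pyr[level], mask_pyr[level]
        grid = f_l.grid
        if u is None:
            u = DisplacementField.zeros_like_grid(grid.shape, grid.spacing, grid.origin)
        else:
            u = prolong_field(u, grid.shape, grid.spacing, grid.origin)

        eps = resolve_edge_parameters(f_l, m_l, config)
        # warp the moving image with the prolonged guess; estimate an
        # additive correction on top of it
        warped = MultiSequenceVolume([warp_image(c, u) for c in m_l.channels],
                                     list(m_l.labels))
        ngf = MultichannelNGF(f_l, warped, s_l, eps)
        base = u.u
        shape = base.shape
        w = config.weights

        def level_objective(v_flat: np.ndarray):
            dval, dgrad = ngf(v_flat.reshape(shape))
            total = DisplacementField(base + v_flat.reshape(shape),
                                      grid.spacing, grid.origin)
            if w.alpha > 0:
                ce, cg = curvature_energy(total)
                dval += w.alpha * ce
                dgrad = dgrad + w.alpha * cg
            if w.volume_control_enabled and w.gamma > 0:
                ve, vg = volume_control_energy(total)
                if not np.isfinite(ve):
                    return np.inf, None
                dval += w.gamma * ve
                dgrad = dgrad + w.gamma * vg
            return dval, dgrad.ravel()

        v_star, hist = lbfgs_minimize(level_objective, np.zeros(base.size),
                                      config.stopping)
        u = DisplacementField(base + v_star.reshape(shape), grid.spacing, grid.origin)
        histories.append(LevelHistory(
            level=level, shape=grid.shape, iterations=hist["iterations"],
            objective_values=hist["objective_values"],
            gradient_norms=hist["gradient_norms"],
            step_lengths=hist["step_lengths"], reason=hist["reason"]))
        log.info("level %d (%s): %d iterations, objective %.6g -> %.6g, stop=%s",
                 level, "x".join(map(str, grid.shape)), hist["iterations"],
                 hist["objective_values"][0], hist["objective_values"][-1],
                 hist["reason"])

    assert u is not None
    # final components on the working grid at the composed field
    eps = resolve_edge_parameters(fixed_pyr[0], moving_pyr[0], config)
    dval, _ = multichannel_distance(fixed_pyr[0], moving_pyr[0], u, mask_pyr[0], eps)
    ce, _ = curvature_energy(u)
    components = {"distance": float(dval), "curvature": float(ce)}
    if config.weights.volume_control_enabled:
        ve, _ = volume_control_energy(u)
        components["volume_control"] = float(ve)
    components["objective"] = (
        components["distance"] + config.weights.alpha * components["curvature"]
        + (config.weights.gamma * components.get("volume_control", 0.0)
           if config.weights.volume_control_enabled else 0.0)
    )

    # back to the caller's grid
    in_grid = fixed.grid
    if u.shape != in_grid.shape or not np.allclose(u.spacing, in_grid.spacing):
        u = prolong_field(u, in_grid.shape, in_grid.spacing, in_grid.origin)
    return RegistrationResult(field=u, levels=histories, final_components=components)
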
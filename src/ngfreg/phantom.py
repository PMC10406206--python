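"""Synthetic longitudinal brain phantom with known ground truth.

The generator emulates the data the registration method targets:
skull-stripped, rigidly pre-aligned, ~1 mm isotropic brain-like volumes
on a cubic grid; one or more MRI "sequences" as distinct monotone
intensity remappings of a shared tissue geometry; a smooth fold-free
ground-truth deformation between the two time points; a resection-like
cavity present only in the fixed (post-operative) image, with its
pathology mask; and paired landmarks in healthy tissue near the cavity.

It is an intensity phantom, not an MR simulation: no k-space, bias
fields or sequence physics — just enough structure (nested "head" and
"ventricle" shapes plus band-passed texture) to give NGF meaningful
gradients everywhere inside the head.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .evaluation import LandmarkSet
from .transform import DisplacementField, folding_fraction, warp_image
from .volume_io import MultiSequenceVolume, PathologyMask, ScalarVolume

__all__ = ["PhantomSpec", "generate_smooth_field", "generate_phantom_pair", "PhantomPair"]

# monotone per-sequence remapping exponents (T1 / T1-CE / T2 / FLAIR flavours)
_SEQUENCE_GAMMAS = (1.0, 0.6, 1.6, 2.4)
_SEQUENCE_LABELS = ("T1", "T1CE", "T2", "FLAIR")


@dataclass
class PhantomSpec:
    """Parameters of one synthetic longitudinal pair.

    Defaults give a 64 mm cube at 1 mm isotropic spacing with a smooth
    deformation of at most 4 mm, a ~8 mm-radius cavity and 20 landmarks —
    a desk-scale analogue of the clinical setting.
    """

    seed: int = 0
    size: int = 64
    n_sequences: int = 1
    amplitude_mm: float = 4.0
    smoothness_vox: float = 8.0
    cavity_radius_mm: float = 8.0
    cavity_center_mm: tuple[float, float, float] | None = None
    n_landmarks: int = 20
    noise_sigma: float = 0.02
    landmark_band_mm: float = 40.0
    shift_fraction: float = 0.5
    shift_scale_mm: float = 14.0
    channel_contrast: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.n_sequences <= 4:
            raise ValueError("n_sequences must be in 1..4")
        if self.size < 16:
            raise ValueError("size must be >= 16")
        if self.amplitude_mm < 0 or self.noise_sigma < 0 or self.cavity_radius_mm < 0:
            raise ValueError("amplitude, noise and cavity radius must be nonnegative")
        if self.smoothness_vox <= 0:
            raise ValueError("smoothness must be positive")
        if not 0 <= self.shift_fraction <= 1:
            raise ValueError("shift_fraction must be in [0, 1]")
        if self.channel_contrast is not None and len(self.channel_contrast) != self.n_sequences:
            raise ValueError("one contrast factor per sequence required")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class PhantomPair:
    """Everything one synthetic case provides."""

    fixed: MultiSequenceVolume
    moving: MultiSequenceVolume
    mask: PathologyMask
    truth: DisplacementField
    fixed_landmarks: LandmarkSet
    moving_landmarks: LandmarkSet
    spec: PhantomSpec


def _smooth_noise_unit(spec: PhantomSpec) -> np.ndarray:
    """Gaussian-filtered white-noise vector field with unit peak magnitude."""
    rng = np.random.default_rng(spec.seed)
    shape = (spec.size,) * 3
    u = np.stack(
        [ndimage.gaussian_filter(rng.standard_normal(shape), spec.smoothness_vox)
         for _ in range(3)], axis=-1)
    peak = float(np.max(np.sqrt(np.sum(u * u, axis=-1))))
    if peak == 0:
        return u
    return u / peak


def _scale_fold_free(u_unit: np.ndarray, amplitude: float) -> DisplacementField:
    """Scale a unit-peak field to ``amplitude`` mm, damping until fold-free."""
    if amplitude == 0 or not np.any(u_unit):
        return DisplacementField(np.zeros(u_unit.shape))
    for _ in range(50):
        field_ = DisplacementField(u_unit * amplitude)
        if folding_fraction(field_) == 0.0:
            return field_
        amplitude *= 0.8
    raise RuntimeError("could not produce a fold-free field; reduce amplitude or "
                       "increase smoothness")


def generate_smooth_field(spec: PhantomSpec) -> DisplacementField:
    """Gaussian-smoothed white-noise field scaled to the requested peak.

    Guaranteed fold-free: if the scaled field folds anywhere, the
    amplitude is damped by 20% and the check repeated.  Deterministic
    per seed.
    """
    return _scale_fold_free(_smooth_noise_unit(spec), spec.amplitude_mm)


def _collapse_unit(spec: PhantomSpec, center: np.ndarray,
                   spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    """Unit-peak smooth collapse toward the resection/tumor site.

    Post-operative brain shift is largest around the resection: tissue
    sinks toward the cavity.  The magnitude profile r/s * exp(1/2 - r^2/(2 s^2))
    vanishes at the center, peaks at one shift scale s and decays
    smoothly outward.
    """
    n = spec.size
    ax = [origin[a] + np.arange(n) * spacing[a] for a in range(3)]
    X = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
    delta = X - center
    r = np.sqrt(np.sum(delta * delta, axis=-1))
    s = spec.shift_scale_mm
    mag = (r / s) * np.exp(0.5 - r * r / (2.0 * s * s))
    dirn = -delta / np.maximum(r, 1e-12)[..., None]
    return mag[..., None] * dirn


def _ground_truth_field(spec: PhantomSpec, center: np.ndarray,
                        spacing: np.ndarray, origin: np.ndarray) -> DisplacementField:
    """Brain-shift-like truth: directed collapse plus a random smooth part."""
    w = spec.shift_fraction
    u = (1.0 - w) * _smooth_noise_unit(spec)
    if w > 0:
        u = u + w * _collapse_unit(spec, center, spacing, origin)
    peak = float(np.max(np.sqrt(np.sum(u * u, axis=-1))))
    if peak > 0:
        u = u / peak
    field_ = _scale_fold_free(u, spec.amplitude_mm)
    return DisplacementField(field_.u, spacing, origin)


def _head_geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Shared tissue field S in [0, 1] and the soft head support.

    Outside the head everything is exactly zero, emulating skull-stripped
    data; inside, nested shapes plus band-passed texture give
    gray/white-matter-like internal edges.
    """
    n = spec.size
    ax = np.arange(n) - (n - 1) / 2.0
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    # slightly anisotropic "head" ellipsoid with a soft ~2.5 voxel edge
    r_head = np.sqrt((X / (0.44 * n)) ** 2 + (Y / (0.40 * n)) ** 2 + (Z / (0.42 * n)) ** 2)
    head = np.clip((1.0 - r_head) / 0.08, 0.0, 1.0)
    # nested "ventricle"
    r_vent = np.sqrt(((X + 0.05 * n) / (0.12 * n)) ** 2 + (Y / (0.09 * n)) ** 2
                     + (Z / (0.14 * n)) ** 2)
    vent = np.clip((1.0 - r_vent) / 0.15, 0.0, 1.0)
    # band-passed noise texture (sulci-like internal edges), unit variance
    raw = rng.standard_normal((n, n, n))
    texture = ndimage.gaussian_filter(raw, 1.5) - ndimage.gaussian_filter(raw, 4.0)
    texture /= max(float(texture.std()), 1e-12)
    s = head * (0.60 - 0.35 * vent + 0.12 * texture)
    return np.clip(s, 0.0, 1.0), head


def _remap(s: np.ndarray, channel: int) -> np.ndarray:
    """Distinct monotone intensity remapping per simulated sequence."""
    return s ** _SEQUENCE_GAMMAS[channel % len(_SEQUENCE_GAMMAS)]


def generate_phantom_pair(spec: PhantomSpec) -> PhantomPair:
    """Build one longitudinal pair with exact ground truth.

    The moving (pre-operative) image is the base anatomy; the fixed
    (post-operative) image is the base warped by the ground-truth field
    (so warping moving by truth reproduces fixed on healthy tissue up to
    noise), with the cavity region blanked to background plus a thin
    bright rim, and the pathology mask is the cavity-plus-rim region
    dilated by one voxel.  Moving landmarks are fixed landmarks mapped through the
    truth field exactly.
    """
    n = spec.size
    spacing = np.ones(3)
    origin = np.zeros(3)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 9173]))

    s, head = _head_geometry(spec, rng)
    contrast = spec.channel_contrast or (1.0,) * spec.n_sequences
    clean_moving = [contrast[c] * _remap(s, c) for c in range(spec.n_sequences)]

    # resection/tumor site: given, or off-center inside the head
    if spec.cavity_center_mm is not None:
        center = np.asarray(spec.cavity_center_mm, dtype=np.float64)
    else:
        center = origin + (n - 1) / 2.0 * spacing + np.array([0.12, -0.10, 0.08]) * n
    truth = _ground_truth_field(spec, center, spacing, origin)

    # fixed = moving ∘ y (healthy tissue corresponds exactly through truth)
    clean_fixed = [
        warp_image(ScalarVolume(cm, spacing, origin), truth).data
        for cm in clean_moving
    ]
    # noise fades out with the head support: skull-stripped background is zero
    head_fixed = warp_image(ScalarVolume(head, spacing, origin), truth).data

    # resection-like cavity: present only in the fixed image
    cavity = np.zeros((n, n, n), dtype=bool)
    if spec.cavity_radius_mm > 0:
        ax = [origin[a] + np.arange(n) * spacing[a] for a in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        dist = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2)
        cavity = dist <= spec.cavity_radius_mm
        if cavity.all():
            raise ValueError("cavity covers the whole volume")
        # thin enhancing rim, fully inside the 1-voxel mask dilation
        rim = (dist > spec.cavity_radius_mm) & (dist <= spec.cavity_radius_mm + 1.0)
        for c in range(spec.n_sequences):
            clean_fixed[c] = clean_fixed[c].copy()
            clean_fixed[c][cavity] = 0.0
            clean_fixed[c][rim] = 0.9 * contrast[c]
        cavity = cavity | rim  # the segmented pathology includes the rim
    mask_arr = ndimage.binary_dilation(cavity, iterations=1) if cavity.any() else cavity

    fixed = MultiSequenceVolume(
        [ScalarVolume(cf + spec.noise_sigma * head_fixed * rng.standard_normal((n, n, n)),
                      spacing, origin) for cf in clean_fixed],
        list(_SEQUENCE_LABELS[: spec.n_sequences]))
    moving = MultiSequenceVolume(
        [ScalarVolume(cm + spec.noise_sigma * head * rng.standard_normal((n, n, n)),
                      spacing, origin) for cm in clean_moving],
        list(_SEQUENCE_LABELS[: spec.n_sequences]))
    mask = PathologyMask(mask_arr.astype(np.uint8), spacing, origin)

    fixed_lm = _pick_landmarks(spec, clean_fixed[0], mask_arr, cavity, spacing, origin, rng)
    moving_lm = _map_through(fixed_lm, truth)
    return PhantomPair(fixed, moving, mask, truth, fixed_lm, moving_lm, spec)


def _pick_landmarks(spec: PhantomSpec, reference: np.ndarray, mask_arr: np.ndarray,
                    cavity: np.ndarray, spacing: np.ndarray, origin: np.ndarray,
                    rng: np.random.Generator) -> LandmarkSet:
    """Sample landmarks at high-gradient healthy voxels near the cavity."""
    n = spec.size
    g = np.stack(np.gradient(reference, *spacing), axis=-1)
    mag = np.sqrt(np.sum(g * g, axis=-1))
    valid = np.ones((n, n, n), dtype=bool)
    border = 2  # keep clear of the volume border
    valid[:border], valid[-border:] = False, False
    valid[:, :border], valid[:, -border:] = False, False
    valid[:, :, :border], valid[:, :, -border:] = False, False
    if mask_arr.any():
        healthy = ~ndimage.binary_dilation(mask_arr, iterations=2)
        valid &= healthy
        # near-pathology annotation band around the cavity
        band_vox = spec.landmark_band_mm / float(spacing.min())
        near = ndimage.binary_dilation(cavity, iterations=int(round(band_vox)))
        valid &= near
    if valid.sum() < spec.n_landmarks:
        raise ValueError("not enough healthy voxels for the requested landmarks")
    mag_valid = np.where(valid, mag, -np.inf)
    k = max(spec.n_landmarks * 50, 500)
    k = min(k, int(valid.sum()))
    flat_idx = np.argpartition(mag_valid.ravel(), -k)[-k:]
    chosen = rng.choice(flat_idx, size=spec.n_landmarks, replace=False)
    ijk = np.stack(np.unravel_index(chosen, (n, n, n)), axis=-1).astype(np.float64)
    pts = origin + ijk * spacing
    labels = [f"L{i:02d}" for i in range(spec.n_landmarks)]
    return LandmarkSet(labels, pts)


def _map_through(pts: LandmarkSet, truth: DisplacementField) -> LandmarkSet:
    from .evaluation import transform_landmarks

    return transform_landmarks(pts, truth)
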
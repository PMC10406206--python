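"""Landmark-based registration accuracy (TRE / mTRE) and paired testing.

Landmarks are annotated in the fixed (post-operative) image's world
frame and paired with counterparts annotated in the moving
(pre-operative) frame.  The estimated deformation maps a fixed-space
point p to p + u(p); the target registration error of a landmark is the
Euclidean distance between that mapped point and its annotated moving
counterpart.  The per-case mean is the TRE, the mean over a cohort of
cases the mTRE.  Paired conditions are compared with the exact Wilcoxon
signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import rankdata

from .transform import DisplacementField, sample_trilinear

__all__ = [
    "LandmarkSet",
    "TREReport",
    "read_landmarks",
    "write_landmarks",
    "transform_landmarks",
    "compute_tre",
    "mtre_over_cohort",
    "wilcoxon_signed_rank",
]


@dataclass
class LandmarkSet:
    """Ordered, labelled 3D points in world mm."""

    labels: list[str]
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != len(self.points):
            raise ValueError("one label per point required")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.labels)


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark CSV with header ``label,x,y,z`` (world mm)."""
    df = pd.read_csv(path)
    required = ["label", "x", "y", "z"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"{path}: expected columns {required}, got {list(df.columns)}")
    return LandmarkSet(list(df["label"].astype(str)), df[["x", "y", "z"]].to_numpy())


def write_landmarks(pts: LandmarkSet, path: str | Path) -> None:
    pd.DataFrame({
        "label": pts.labels,
        "x": pts.points[:, 0],
        "y": pts.points[:, 1],
        "z": pts.points[:, 2],
    }).to_csv(path, index=False)


def transform_landmarks(pts: LandmarkSet, u: DisplacementField) -> LandmarkSet:
    """Map each fixed-space point p to p + u(p), u trilinearly interpolated."""
    lo = u.origin - u.spacing / 2
    hi = lo + np.array(u.shape) * u.spacing
    if np.any(pts.points < lo) or np.any(pts.points > hi):
        raise ValueError("landmark outside the displacement field's world extent")
    vox = (pts.points - u.origin) / u.spacing
    disp = np.stack([sample_trilinear(u.u[..., k], vox) for k in range(3)], axis=-1)
    return LandmarkSet(list(pts.labels), pts.points + disp)


@dataclass
class TREReport:
    """Per-landmark registration errors (mm) for one image pair."""

    labels: list[str]
    distances: np.ndarray          # with the field applied (or baseline if none)
    baseline_distances: np.ndarray  # without any field
    mean: float = field(init=False)
    baseline_mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.float64)
        self.baseline_distances = np.asarray(self.baseline_distances, dtype=np.float64)
        if np.any(self.distances < 0) or np.any(self.baseline_distances < 0):
            raise ValueError("distances must be nonnegative")
        self.mean = float(np.mean(self.distances))
        self.baseline_mean = float(np.mean(self.baseline_distances))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "label": self.labels,
            "baseline_mm": self.baseline_distances,
            "distance_mm": self.distances,
        })
        df.loc[len(df)] = ["mean", self.baseline_mean, self.mean]
        return df


def compute_tre(fixed_pts: LandmarkSet, moving_pts: LandmarkSet,
                u: DisplacementField | None = None) -> TREReport:
    """Per-landmark Euclidean errors and their mean.

    With a field, fixed-space landmarks are mapped through y = id + u
    before measuring distances to their moving-space counterparts;
    without one the report is the pre-registration baseline.
    """
    if len(fixed_pts) != len(moving_pts):
        raise ValueError("paired landmark sets must have equal length")
    if fixed_pts.labels != moving_pts.labels:
        raise ValueError("paired landmark sets must have matching labels in order")
    baseline = np.linalg.norm(fixed_pts.points - moving_pts.points, axis=1)
    if u is None:
        return TREReport(list(fixed_pts.labels), baseline, baseline)
    mapped = transform_landmarks(fixed_pts, u)
    dist = np.linalg.norm(mapped.points - moving_pts.points, axis=1)
    return TREReport(list(fixed_pts.labels), dist, baseline)


def mtre_over_cohort(reports: list[TREReport]) -> float:
    """Mean of the per-case mean TREs (mm)."""
    if not reports:
        raise ValueError("empty cohort")
    return float(np.mean([r.mean for r in reports]))


def _exact_signed_rank_tails(ranks2: np.ndarray, w2: int) -> tuple[float, float]:
    """P(W+ <= w) and P(W+ >= w) over all 2^n sign assignments.

    ``ranks2`` are midranks doubled to integers; the distribution of the
    doubled positive-rank sum is built by convolution, which enumerates
    the 2^n assignments exactly.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    return float(counts[: w2 + 1].sum()), float(counts[w2:].sum())


def wilcoxon_signed_rank(paired_a, paired_b, exact_max_n: int = 25):
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded (Wilcoxon's original treatment); at
    least 5 nonzero differences are required.  Ties receive midranks.
    For n <= ``exact_max_n`` the p-value is exact over all 2^n sign
    assignments; beyond that a normal approximation with tie-corrected
    variance and continuity correction is used.

    Returns ``(W_plus, p_value, "two-sided")``.
    """
    a = np.asarray(paired_a, dtype=np.float64)
    b = np.asarray(paired_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D arrays of equal length")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all paired differences are zero; the test is undefined")
    n = d.size
    if n < 5:
        raise ValueError(f"need at least 5 nonzero differences, got {n}")
    ranks = rankdata(np.abs(d))  # midranks
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        ranks2 = np.round(2.0 * ranks).astype(np.int64)
        w2 = int(round(2.0 * w_plus))
        p_lo, p_hi = _exact_signed_rank_tails(ranks2, w2)
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        return w_plus, p, "two-sided"

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_corr = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    if var <= 0:
        raise ValueError("degenerate variance in the normal approximation")
    delta = w_plus - mean
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var)
    p = min(1.0, 2.0 * (1.0 - float(ndtr(abs(z)))))
    return w_plus, p, "two-sided"
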
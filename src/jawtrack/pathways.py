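"""Derived kinematics and method comparison.

Propagates landmark pathways through per-frame transforms, builds inclination
and instantaneous-center-of-rotation series, and compares two tracking methods
by per-frame pathway distances, upper-third medians and one-sided
threshold tests (Wilcoxon signed-rank with a Shapiro-Wilk normality check
reported alongside).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, InvalidInputError
from .geometry2d import DEFAULT_ICR_MIN_ROTATION_DEG, compute_icr

__all__ = [
    "Pathway",
    "ThresholdTestResult",
    "PathComparison",
    "ComparisonReport",
    "propagate_point",
    "inclination_series",
    "icr_pathway",
    "path_distance_series",
    "upper_third_median",
    "threshold_test",
    "compare_methods",
]

DEFAULT_DISTANCE_THRESHOLD_MM = 1.0
DEFAULT_INCLINATION_THRESHOLD_DEG = 1.0


@dataclass
class Pathway:
    """One 2D point per tracked frame; NaN rows mark undefined entries (ICR)."""

    frames: np.ndarray
    points: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (len(self.frames), 2):
            raise InvalidInputError("pathway points must be (n_frames, 2)")

    @property
    def defined(self) -> np.ndarray:
        return np.all(np.isfinite(self.points), axis=1)


def propagate_point(transforms, point, name: str = "") -> Pathway:
    """Apply each per-frame transform to a frame-1 point."""
    p = np.asarray(point, dtype=float)
    pts = np.vstack([t.apply(p[None, :])[0] for t in transforms])
    return Pathway(frames=np.arange(1, len(transforms) + 1), points=pts, name=name)


def inclination_series(transforms) -> np.ndarray:
    """Rotation angle of each frame relative to frame 1, in degrees."""
    return np.array([math.degrees(t.theta) for t in transforms])


def icr_pathway(transforms, min_rotation_deg: float = DEFAULT_ICR_MIN_ROTATION_DEG) -> Pathway:
    """Frame-to-frame instantaneous center of rotation; NaN where undefined."""
    if len(transforms) < 2:
        raise InsufficientDataError("need >= 2 frames for an ICR pathway")
    pts = np.full((len(transforms), 2), np.nan)
    for i in range(1, len(transforms)):
        c = compute_icr(transforms[i - 1], transforms[i], min_rotation_deg)
        if c is not None:
            pts[i] = c
    return Pathway(frames=np.arange(1, len(transforms) + 1), points=pts, name="ICR")


def path_distance_series(a: Pathway, b: Pathway) -> np.ndarray:
    """Per-frame Euclidean distance; NaN where either entry is undefined."""
    if len(a.frames) != len(b.frames) or np.any(a.frames != b.frames):
        raise InvalidInputError("pathways cover different frames")
    d = np.linalg.norm(a.points - b.points, axis=1)
    if not np.any(np.isfinite(d)):
        raise InvalidInputError("no frame where both pathways are defined")
    return d


def upper_third_median(values) -> float:
    """Median of the largest ``ceil(n/3)`` values ("most distant third")."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 3:
        raise InsufficientDataError("need >= 3 values")
    k = math.ceil(len(v) / 3)
    top = np.sort(v)[::-1][:k]
    return float(np.median(top))


@dataclass
class ThresholdTestResult:
    """One-sided Wilcoxon signed-rank of values against a threshold."""

    p_value: float
    statistic: float
    n: int
    shapiro_p: float | None
    degenerate: bool = False


def threshold_test(values, threshold: float, alternative: str = "greater") -> ThresholdTestResult:
    """Test whether values exceed a threshold (right tail by default).

    Wilcoxon signed-rank on ``values - threshold`` with zero differences
    dropped; the exact null distribution for n <= 25 and the normal
    approximation above.  A Shapiro-Wilk p-value is reported alongside but
    does not change the test used.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 5:
        raise InsufficientDataError("need >= 5 observations")
    d = v - threshold
    shapiro_p = float(stats.shapiro(d).pvalue) if len(d) >= 3 and np.ptp(d) > 0 else None
    nonzero = d[d != 0]
    if len(nonzero) == 0:
        return ThresholdTestResult(1.0, 0.0, 0, shapiro_p, degenerate=True)
    method = "exact" if len(nonzero) <= 25 else "approx"
    res = stats.wilcoxon(nonzero, alternative=alternative, method=method)
    return ThresholdTestResult(
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        n=len(nonzero),
        shapiro_p=shapiro_p,
    )


@dataclass
class PathComparison:
    distances: np.ndarray
    upper_third_median: float
    test: ThresholdTestResult
    threshold: float

    def to_dict(self) -> dict:
        return {
            "upper_third_median": self.upper_third_median,
            "threshold": self.threshold,
            "p_value": self.test.p_value,
            "shapiro_p": self.test.shapiro_p,
            "n": self.test.n,
            "n_frames_defined": int(np.sum(np.isfinite(self.distances))),
        }


@dataclass
class ComparisonReport:
    """Per-landmark pathway comparison plus the inclination comparison."""

    landmarks: dict = field(default_factory=dict)
    inclination: PathComparison | None = None

    def to_dict(self) -> dict:
        out = {name: c.to_dict() for name, c in self.landmarks.items()}
        if self.inclination is not None:
            out["inclination"] = self.inclination.to_dict()
        return out


def compare_methods(
    transforms_a,
    transforms_b,
    landmark_points: dict,
    icr_min_rotation_deg: float = DEFAULT_ICR_MIN_ROTATION_DEG,
    distance_threshold_mm: float = DEFAULT_DISTANCE_THRESHOLD_MM,
    inclination_threshold_deg: float = DEFAULT_INCLINATION_THRESHOLD_DEG,
) -> ComparisonReport:
    """Compare two tracking methods' transforms.

    ``landmark_points`` maps landmark name -> frame-1 position (typically
    condyle_superior, condyle_center and gonion); each is propagated through
    both transform series.  ICR pathways are compared on frames where both are
    defined; the inclination comparison uses the absolute per-frame angle
    difference in degrees.
    """
    report = ComparisonReport()
    for name, point in landmark_points.items():
        pa = propagate_point(transforms_a, point, name)
        pb = propagate_point(transforms_b, point, name)
        d = path_distance_series(pa, pb)
        report.landmarks[name] = PathComparison(
            distances=d,
            upper_third_median=upper_third_median(d),
            test=threshold_test(d, distance_threshold_mm),
            threshold=distance_threshold_mm,
        )
    try:
        ia = icr_pathway(transforms_a, icr_min_rotation_deg)
        ib = icr_pathway(transforms_b, icr_min_rotation_deg)
        d = path_distance_series(ia, ib)
        report.landmarks["ICR"] = PathComparison(
            distances=d,
            upper_third_median=upper_third_median(d),
            test=threshold_test(d, distance_threshold_mm),
            threshold=distance_threshold_mm,
        )
    except (InvalidInputError, InsufficientDataError):
        pass  # ICR undefined on (nearly) every frame; excluded rather than imputed
    dinc = np.abs(inclination_series(transforms_a) - inclination_series(transforms_b))
    report.inclination = PathComparison(
        distances=dinc,
        upper_third_median=upper_third_median(dinc),
        test=threshold_test(dinc, inclination_threshold_deg),
        threshold=inclination_threshold_deg,
    )
    return report
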
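"""Annotation data model: per-slice mandible areas and contours, named
landmarks, keyframe selection/interpolation and mask rasterization.

Frames are 1-based everywhere in the public API (matching "first frame"
language in clinical use); coordinates are millimetres in the image frame
described in :mod:`jawtrack.geometry2d`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DegenerateConfigurationError,
    EmptyMaskError,
    InvalidInputError,
    MalformedAnnotationError,
    OutOfRangeError,
)
from .geometry2d import fit_circle_pratt

__all__ = [
    "TEMPORAL_LANDMARKS",
    "MANDIBULAR_LANDMARKS",
    "LANDMARK_NAMES",
    "KEYFRAME_STRIDE",
    "LandmarkSet",
    "KeyframeTrack",
    "AreaAnnotation",
    "StudyAnnotation",
    "select_keyframes",
    "interpolate_landmarks",
    "points_in_polygon",
    "rasterize_polygon",
    "rasterize_area",
    "condyle_center",
]

#: Two static reference landmarks on the temporal bone.
TEMPORAL_LANDMARKS = ("eminence_crest_inferior", "fossa_superior")
#: Three moving landmarks on the mandible; these drive the rough transform.
MANDIBULAR_LANDMARKS = ("condyle_superior", "incisura_inferior", "gonion")
LANDMARK_NAMES = TEMPORAL_LANDMARKS + MANDIBULAR_LANDMARKS

#: Keyframes are taken at every multiple of this stride between scan bounds.
KEYFRAME_STRIDE = 25


@dataclass
class LandmarkSet:
    """The five named annotation landmarks of one keyframe, in mm."""

    points: dict

    def __post_init__(self):
        missing = set(LANDMARK_NAMES) - set(self.points)
        if missing:
            raise MalformedAnnotationError(f"missing landmarks: {sorted(missing)}")
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}
        for name, p in self.points.items():
            if p.shape != (2,) or not np.all(np.isfinite(p)):
                raise MalformedAnnotationError(f"landmark {name!r} is not a finite 2D point")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def array(self, names=MANDIBULAR_LANDMARKS) -> np.ndarray:
        """Stack the named landmarks into an ``(k, 2)`` array."""
        return np.stack([self.points[n] for n in names])


@dataclass
class KeyframeTrack:
    """Sparse landmark annotations: one :class:`LandmarkSet` per keyframe."""

    keyframe_indices: list
    landmark_sets: list

    def __post_init__(self):
        idx = list(self.keyframe_indices)
        if len(idx) != len(self.landmark_sets):
            raise MalformedAnnotationError("keyframe index / landmark set count mismatch")
        if len(idx) < 1:
            raise MalformedAnnotationError("need at least one keyframe")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise MalformedAnnotationError("keyframe indices must be strictly increasing")
        if idx[0] != 1:
            raise MalformedAnnotationError("first keyframe must be frame 1")
        self.keyframe_indices = idx


@dataclass
class AreaAnnotation:
    """Per-slice drawn regions: mandible area polygon plus condyle and fossa contours."""

    slice_id: int
    mandible_polygon: np.ndarray
    condyle_contour: np.ndarray
    fossa_contour: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    def __post_init__(self):
        self.mandible_polygon = np.asarray(self.mandible_polygon, dtype=float)
        self.condyle_contour = np.asarray(self.condyle_contour, dtype=float)
        self.fossa_contour = np.asarray(self.fossa_contour, dtype=float)
        if self.mandible_polygon.ndim != 2 or self.mandible_polygon.shape[0] < 3:
            raise MalformedAnnotationError("mandible polygon needs >= 3 vertices")


@dataclass
class StudyAnnotation:
    """Everything the rater produces for one study."""

    pixel_spacing: tuple
    n_frames: int
    slices: list
    keyframes: KeyframeTrack
    cycle: tuple

    def __post_init__(self):
        if self.n_frames < 1:
            raise MalformedAnnotationError("n_frames must be >= 1")
        if self.keyframes.keyframe_indices[-1] != self.n_frames and self.n_frames > 1:
            raise MalformedAnnotationError("last keyframe must be the last frame")
        first, last = self.cycle
        if not (1 <= first <= last <= self.n_frames):
            raise MalformedAnnotationError("cycle bounds outside the scan")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def middle_slice_id(self) -> int:
        ids = sorted(a.slice_id for a in self.slices)
        return ids[len(ids) // 2]

    def area(self, slice_id: int) -> AreaAnnotation:
        for a in self.slices:
            if a.slice_id == slice_id:
                return a
        raise MalformedAnnotationError(f"no area annotation for slice {slice_id}")


def select_keyframes(n_frames: int, cycle_first: int, cycle_last: int) -> list:
    """Keyframe rule: scan bounds, movement-cycle bounds, and every
    ``KEYFRAME_STRIDE``-th frame strictly in between, de-duplicated and sorted.
    """
    if not (1 <= cycle_first < cycle_last <= n_frames):
        raise InvalidInputError(
            f"need 1 <= cycle_first < cycle_last <= n_frames, got ({n_frames}, {cycle_first}, {cycle_last})"
        )
    frames = {1, n_frames, cycle_first, cycle_last}
    frames.update(range(KEYFRAME_STRIDE, n_frames, KEYFRAME_STRIDE))
    return sorted(frames)


def interpolate_landmarks(track: KeyframeTrack, frame: int) -> LandmarkSet:
    """Linear per-coordinate interpolation between the two bracketing keyframes.

    Exact at keyframes; ``frame`` must be an integer within the keyframe range.
    """
    idx = track.keyframe_indices
    if not (idx[0] <= frame <= idx[-1]):
        raise OutOfRangeError(f"frame {frame} outside keyframe range [{idx[0]}, {idx[-1]}]")
    import bisect

    pos = bisect.bisect_left(idx, frame)
    if pos < len(idx) and idx[pos] == frame:
        return LandmarkSet(dict(track.landmark_sets[pos].points))
    lo, hi = pos - 1, pos
    k0, k1 = idx[lo], idx[hi]
    w = (frame - k0) / (k1 - k0)
    pts = {}
    for name in LANDMARK_NAMES:
        p0 = track.landmark_sets[lo][name]
        p1 = track.landmark_sets[hi][name]
        pts[name] = (1.0 - w) * p0 + w * p1
    return LandmarkSet(pts)


def points_in_polygon(points, polygon) -> np.ndarray:
    """Even-odd (crossing number) point-in-polygon test, vectorized.

    Edges are treated half-open in ``y`` so points on shared horizontal levels
    are counted exactly once; the polygon is implicitly closed.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or len(poly) < 3:
        raise InvalidInputError("polygon needs >= 3 vertices")
    x, y = pts[:, 0][:, None], pts[:, 1][:, None]
    x1, y1 = poly[:, 0], poly[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    crosses = ((y1 <= y) & (y < y2)) | ((y2 <= y) & (y < y1))
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = x1 + (y - y1) * (x2 - x1) / np.where(y2 == y1, np.inf, y2 - y1)
    hits = crosses & (xint > x)
    return (hits.sum(axis=1) % 2).astype(bool)


def rasterize_polygon(polygon_mm, image_shape, pixel_spacing) -> np.ndarray:
    """Boolean mask of pixels whose *center* lies inside the polygon (even-odd).

    ``image_shape`` is ``(rows, cols)``; ``pixel_spacing`` is ``(sx, sy)`` mm.
    """
    poly = np.asarray(polygon_mm, dtype=float)
    rows, cols = image_shape
    sx, sy = float(pixel_spacing[0]), float(pixel_spacing[1])
    mask = np.zeros((rows, cols), dtype=bool)
    # restrict the test to the polygon's bounding box
    c0 = max(0, int(np.ceil(poly[:, 0].min() / sx)))
    c1 = min(cols - 1, int(np.floor(poly[:, 0].max() / sx)))
    r0 = max(0, int(np.ceil(poly[:, 1].min() / sy)))
    r1 = min(rows - 1, int(np.floor(poly[:, 1].max() / sy)))
    if c0 > c1 or r0 > r1:
        raise EmptyMaskError("polygon covers no pixel centers")
    cc, rr = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    centers = np.column_stack([cc.ravel() * sx, rr.ravel() * sy])
    inside = points_in_polygon(centers, poly)
    if not inside.any():
        raise EmptyMaskError("polygon covers no pixel centers")
    mask[rr.ravel()[inside], cc.ravel()[inside]] = True
    return mask


def rasterize_area(area: AreaAnnotation, image_shape, pixel_spacing) -> np.ndarray:
    """Rasterize an area annotation's mandible polygon."""
    return rasterize_polygon(area.mandible_polygon, image_shape, pixel_spacing)


def condyle_center(area: AreaAnnotation) -> np.ndarray:
    """Center of the Pratt circle fitted to the condyle contour."""
    contour = area.condyle_contour
    if len(contour) < 3:
        raise DegenerateConfigurationError("condyle contour needs >= 3 vertices")
    return fit_circle_pratt(contour).center
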
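"""Synthetic phantom with ground-truth motion.

Renders a bright condyle disc attached to a ramus bar over a static
temporal-bone background, moved per frame by a rigid opening-closing
trajectory: translation of the condyle center along a circular "eminence"
arc plus rotation about it, both modulated by a sin^2 profile peaking at the
maximum-mouth-opening frame.  Optional through-plane shape change is modeled
as a shrink of the shape's support peaking at MMO, and additive Gaussian noise
emulates acquisition noise.  Identical spec and seed give bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely.geometry

from .annotation import (
    AreaAnnotation,
    KeyframeTrack,
    LandmarkSet,
    StudyAnnotation,
    select_keyframes,
)
from .exceptions import InvalidInputError, OutOfBoundsError
from .geometry2d import RigidTransform2D, rotation_matrix
from .io import FrameSequence

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "opening_profile",
    "generate_phantom",
    "perturb_landmarks",
]

# intensity amplitudes (arbitrary grey units)
CONDYLE_AMPLITUDE = 200.0
RAMUS_AMPLITUDE = 160.0
BACKGROUND_AMPLITUDE = 110.0
#: The drawn mandible area extends this far beyond the bone outline.
AREA_MARGIN_MM = 3.0
#: Amplitude of the static bone texture (grey units).
TEXTURE_AMPLITUDE = 25.0
#: The section change is concentrated near maximal opening: the deformation is
#: modulated by the opening profile raised to this power (still peaking at MMO).
DEFORMATION_PROFILE_EXPONENT = 3


@dataclass(frozen=True)
class PhantomSpec:
    """Acquisition-like phantom parameters (defaults mirror 0.75 mm rt-MRI)."""

    image_shape: tuple = (128, 128)
    pixel_spacing: tuple = (0.75, 0.75)
    n_frames: int = 100
    n_slices: int = 3
    frame_rate: float = 10.0
    slice_gap: float = 6.0
    max_translation_mm: float = 10.0
    max_rotation_deg: float = 30.0
    mmo_frame: int | None = None
    deformation_amplitude: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise InvalidInputError("need at least 2 frames")
        if not (self.pixel_spacing[0] > 0 and self.pixel_spacing[1] > 0):
            raise InvalidInputError("pixel spacing must be positive")
        if not (0.0 <= self.deformation_amplitude <= 0.2):
            raise InvalidInputError("deformation_amplitude must be in [0, 0.2]")

    @property
    def mmo(self) -> int:
        return self.mmo_frame if self.mmo_frame is not None else (self.n_frames + 1) // 2

    @property
    def fov_mm(self) -> tuple:
        return (
            (self.image_shape[1] - 1) * self.pixel_spacing[0],
            (self.image_shape[0] - 1) * self.pixel_spacing[1],
        )


@dataclass
class PhantomGroundTruth:
    """True per-frame transforms, landmark tracks and the generated annotation."""

    transforms: list
    landmark_tracks: dict
    annotation: StudyAnnotation
    condyle_center: np.ndarray
    spec: PhantomSpec
    geometry: dict = field(default_factory=dict)


def opening_profile(n_frames: int, mmo_frame: int) -> np.ndarray:
    """sin^2 open-close profile: 0 at the scan bounds, 1 at ``mmo_frame``."""
    t = np.arange(1, n_frames + 1, dtype=float)
    s = np.zeros(n_frames)
    if mmo_frame > 1:
        up = t <= mmo_frame
        s[up] = np.sin(0.5 * np.pi * (t[up] - 1) / (mmo_frame - 1)) ** 2
    if mmo_frame < n_frames:
        down = t > mmo_frame
        s[down] = np.sin(0.5 * np.pi * (n_frames - t[down]) / (n_frames - mmo_frame)) ** 2
    s[mmo_frame - 1] = 1.0
    return s


def _geometry(spec: PhantomSpec) -> dict:
    """Anatomical layout in mm, scaled to the field of view."""
    w, h = spec.fov_mm
    g = {
        "condyle_center": np.array([0.625 * w, 0.40 * h]),
        "gonion": np.array([0.54 * w, 0.75 * h]),
        "condyle_radius": 0.047 * w,
        "ramus_half_width": 0.042 * w,
        "eminence_center": np.array([0.56 * w, 0.21 * h]),
        "bg_centers": [np.array([0.50 * w, 0.215 * h]), np.array([0.66 * w, 0.235 * h])],
        "bg_radius": 0.047 * w,
        "outer_slice_factor": 0.85,
    }
    g["condyle_superior"] = g["condyle_center"] - np.array([0.0, g["condyle_radius"]])
    g["incisura_inferior"] = np.array([0.56 * w, 0.47 * h])
    g["eminence_crest_inferior"] = np.array([0.50 * w, 0.31 * h])
    g["fossa_superior"] = np.array([0.645 * w, 0.27 * h])
    return g


def _slice_factor(spec: PhantomSpec, slice_id: int, geometry: dict) -> float:
    middle = (spec.n_slices + 1) // 2
    return 1.0 if slice_id == middle else geometry["outer_slice_factor"]


def _trajectory(spec: PhantomSpec, geometry: dict) -> list:
    """Per-frame rigid transforms: arc translation of the condyle + rotation."""
    c1 = geometry["condyle_center"]
    e = geometry["eminence_center"]
    radial = c1 - e
    rho = float(np.linalg.norm(radial))
    dphi = 2.0 * math.asin(min(1.0, spec.max_translation_mm / (2.0 * rho)))
    s = opening_profile(spec.n_frames, spec.mmo)
    transforms = []
    for st in s:
        theta = math.radians(spec.max_rotation_deg) * st
        c_t = e + rotation_matrix(dphi * st) @ radial
        t = c_t - rotation_matrix(theta) @ c1
        transforms.append(RigidTransform2D(theta, float(t[0]), float(t[1])))
    return transforms


def _segment_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    u = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
    proj = a + u[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1)


def _mandible_intensity(pts: np.ndarray, geometry: dict, factor: float, deform: float) -> np.ndarray:
    """Smooth compact-support intensity of the mandible shape in reference pose.

    ``deform`` erodes the condyle section while dilating the ramus section —
    the kind of through-plane section change no global rigid-plus-diagonal
    scaling can compensate.
    """
    c1 = geometry["condyle_center"]
    g1 = geometry["gonion"]
    rc = geometry["condyle_radius"] * factor * (1.0 - deform)
    w = geometry["ramus_half_width"] * factor * (1.0 + deform)
    dc = np.linalg.norm(pts - c1, axis=1)
    ic = CONDYLE_AMPLITUDE * np.clip(1.0 - (dc / rc) ** 2, 0.0, None)
    db = _segment_distance(pts, c1, g1)
    ib = RAMUS_AMPLITUDE * np.clip(1.0 - (db / w) ** 2, 0.0, None)
    envelope = np.maximum(ic, ib)
    # static trabecular-like texture fixed to the bone (reference coordinates),
    # tapered by the envelope so the compact support is unchanged
    u, v = pts[:, 0] - c1[0], pts[:, 1] - c1[1]
    texture = (
        np.sin(2.0 * np.pi * u / 5.3 + 0.7) * np.sin(2.0 * np.pi * v / 4.1 + 1.9)
        + 0.6 * np.sin(2.0 * np.pi * (u + 0.8 * v) / 7.9)
    )
    return envelope + TEXTURE_AMPLITUDE * texture * np.clip(envelope / 80.0, 0.0, 1.0)


def _background_intensity(pts: np.ndarray, geometry: dict) -> np.ndarray:
    out = np.zeros(len(pts))
    for c in geometry["bg_centers"]:
        d = np.linalg.norm(pts - c, axis=1)
        out = np.maximum(
            out, BACKGROUND_AMPLITUDE * np.clip(1.0 - (d / geometry["bg_radius"]) ** 2, 0.0, None)
        )
    return out


def _slice_polygon(geometry: dict, factor: float, margin_mm: float = 0.0) -> np.ndarray:
    """Outline of the mandible support: condyle disc ∪ ramus bar (shapely union).

    ``margin_mm`` grows the outline the way a rater draws the area slightly
    around the bone; flat background pixels inside the margin are later removed
    by the near-vertical filter.
    """
    c1 = geometry["condyle_center"]
    g1 = geometry["gonion"]
    disc = shapely.geometry.Point(c1).buffer(geometry["condyle_radius"] * factor, quad_segs=24)
    bar = shapely.geometry.LineString([c1, g1]).buffer(
        geometry["ramus_half_width"] * factor, quad_segs=12
    )
    union = disc.union(bar)
    if margin_mm > 0:
        union = union.buffer(margin_mm, quad_segs=8)
    coords = np.asarray(union.exterior.coords)[:-1]  # drop the closing duplicate
    return coords


def _condyle_arc(geometry: dict, factor: float, n: int = 24) -> np.ndarray:
    """Open arc over the condyle head (upper part; y points down)."""
    c1 = geometry["condyle_center"]
    rc = geometry["condyle_radius"] * factor
    phi = np.linspace(math.radians(-170.0), math.radians(-10.0), n)
    return c1 + rc * np.column_stack([np.cos(phi), np.sin(phi)])


def _fossa_arc(geometry: dict, n: int = 16) -> np.ndarray:
    c1 = geometry["condyle_center"]
    r = geometry["condyle_radius"] + 1.5
    phi = np.linspace(math.radians(-160.0), math.radians(-20.0), n)
    return c1 + r * np.column_stack([np.cos(phi), np.sin(phi)])


def _build_annotation(spec: PhantomSpec, geometry: dict, transforms: list) -> StudyAnnotation:
    slices = []
    for sid in range(1, spec.n_slices + 1):
        factor = _slice_factor(spec, sid, geometry)
        slices.append(
            AreaAnnotation(
                slice_id=sid,
                mandible_polygon=_slice_polygon(geometry, factor, margin_mm=AREA_MARGIN_MM),
                condyle_contour=_condyle_arc(geometry, factor),
                fossa_contour=_fossa_arc(geometry),
            )
        )
    if spec.n_frames >= 4:
        cycle = (2, spec.n_frames - 1)
    else:
        cycle = (1, spec.n_frames)
    # keyframe rule plus one keyframe at MMO (a rater always marks the apex;
    # without it, short scans have no keyframe anywhere near peak excursion)
    keyframe_idx = sorted(set(select_keyframes(spec.n_frames, cycle[0], cycle[1])) | {spec.mmo})
    moving = {name: geometry[name] for name in ("condyle_superior", "incisura_inferior", "gonion")}
    static = {name: geometry[name] for name in ("eminence_crest_inferior", "fossa_superior")}
    sets = []
    for f in keyframe_idx:
        t = transforms[f - 1]
        pts = {name: t.apply(p[None, :])[0] for name, p in moving.items()}
        pts.update({name: p.copy() for name, p in static.items()})
        sets.append(LandmarkSet(pts))
    return StudyAnnotation(
        pixel_spacing=tuple(spec.pixel_spacing),
        n_frames=spec.n_frames,
        slices=slices,
        keyframes=KeyframeTrack(keyframe_idx, sets),
        cycle=cycle,
    )


def generate_phantom(spec: PhantomSpec):
    """Render the phantom sequence; returns ``(FrameSequence, PhantomGroundTruth)``."""
    geometry = _geometry(spec)
    transforms = _trajectory(spec, geometry)
    s = opening_profile(spec.n_frames, spec.mmo)

    # field-of-view check on the (largest) transformed outline
    poly = _slice_polygon(geometry, 1.0)
    w_mm, h_mm = spec.fov_mm
    for f, t in enumerate(transforms, start=1):
        moved = t.apply(poly)
        if (
            moved[:, 0].min() < 0
            or moved[:, 1].min() < 0
            or moved[:, 0].max() > w_mm
            or moved[:, 1].max() > h_mm
        ):
            raise OutOfBoundsError(f"mandible leaves the field of view at frame {f}")

    rows, cols = spec.image_shape
    cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
    centers = np.column_stack(
        [cc.ravel() * spec.pixel_spacing[0], rr.ravel() * spec.pixel_spacing[1]]
    )
    data = np.zeros((spec.n_frames, spec.n_slices, rows, cols))
    bg = {
        sid: _background_intensity(centers, geometry).reshape(rows, cols)
        for sid in range(1, spec.n_slices + 1)
    }
    for f, t in enumerate(transforms, start=1):
        inv = t.inverse()
        back = inv.apply(centers)
        deform = spec.deformation_amplitude * s[f - 1] ** DEFORMATION_PROFILE_EXPONENT
        for sid in range(1, spec.n_slices + 1):
            factor = _slice_factor(spec, sid, geometry)
            mand = _mandible_intensity(back, geometry, factor, deform).reshape(rows, cols)
            data[f - 1, sid - 1] = np.maximum(mand, bg[sid])
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)

    annotation = _build_annotation(spec, geometry, transforms)
    tracks = {}
    moving = ("condyle_superior", "incisura_inferior", "gonion")
    for name in moving:
        tracks[name] = np.vstack([t.apply(geometry[name][None, :])[0] for t in transforms])
    tracks["condyle_center"] = np.vstack(
        [t.apply(geometry["condyle_center"][None, :])[0] for t in transforms]
    )
    for name in ("eminence_crest_inferior", "fossa_superior"):
        tracks[name] = np.tile(geometry[name], (spec.n_frames, 1))

    frames = FrameSequence(
        data=data,
        pixel_spacing=tuple(spec.pixel_spacing),
        frame_rate=spec.frame_rate,
        slice_gap=spec.slice_gap,
    )
    truth = PhantomGroundTruth(
        transforms=transforms,
        landmark_tracks=tracks,
        annotation=annotation,
        condyle_center=geometry["condyle_center"],
        spec=spec,
        geometry=geometry,
    )
    return frames, truth


def perturb_landmarks(truth: PhantomGroundTruth, sigma_px: float, seed: int) -> pd.DataFrame:
    """Noisy manual landmark table (frame, cs_x, cs_y, go_x, go_y) in mm.

    Adds isotropic Gaussian noise of ``sigma_px`` pixels (converted to mm) to
    the true condylar-superior and gonion tracks; ``sigma_px == 0`` returns the
    truth exactly.
    """
    if sigma_px < 0:
        raise InvalidInputError("sigma must be >= 0")
    cs = truth.landmark_tracks["condyle_superior"].copy()
    go = truth.landmark_tracks["gonion"].copy()
    n = len(cs)
    if sigma_px > 0:
        rng = np.random.default_rng(seed)
        spacing = np.asarray(truth.spec.pixel_spacing)
        cs = cs + rng.normal(0.0, sigma_px, size=(n, 2)) * spacing
        go = go + rng.normal(0.0, sigma_px, size=(n, 2)) * spacing
    return pd.DataFrame(
        {
            "frame": np.arange(1, n + 1),
            "cs_x": cs[:, 0],
            "cs_y": cs[:, 1],
            "go_x": go[:, 0],
            "go_y": go[:, 1],
        }
    )
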
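"""LMS registration core: nearest-point pairing, superimposition error,
weighted point-to-plane rigid fitting, diagonal-scaling refinement, per-frame
convergence loop and whole-sequence tracking.

The registration is 2D acting on a 3D representation: the transform moves only
the (x, y) coordinates while the lifted grey coordinate z is compared but never
transformed.  The optimized objective is the weighted squared distance of each
model point to its paired observed point, projected onto the model point's
surface normal; the reported superimposition error is the unweighted mean
absolute projected distance (dimensionless by construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .annotation import (
    MANDIBULAR_LANDMARKS,
    StudyAnnotation,
    interpolate_landmarks,
    rasterize_polygon,
)
from .exceptions import (
    DegenerateGeometryError,
    EmptyMaskError,
    InsufficientDataError,
    InvalidInputError,
    ZeroSpreadError,
)
from .extraction import (
    DEFAULT_CONDYLE_WEIGHT,
    DEFAULT_MIDDLE_SLICE_WEIGHT,
    DEFAULT_VERTICAL_FILTER_DEG,
    NormalizationParams,
    PointCloud,
    assign_weights,
    compute_intensity_scale,
    estimate_normals,
    filter_near_vertical,
    lift_to_cloud,
)
from .geometry2d import (
    DEFAULT_ICR_MIN_ROTATION_DEG,
    RigidTransform2D,
    ScaledTransform2D,
    fit_rigid_svd,
    rotation_matrix,
)

__all__ = [
    "RegistrationConfig",
    "Pairing",
    "FrameRegistration",
    "TrackingResult",
    "lifted_apply",
    "pair_points",
    "superimposition_error",
    "fit_rigid_point_to_plane",
    "fit_scaling",
    "register_frame",
    "build_model_cloud",
    "extract_observed_cloud",
    "rough_transform",
    "error_series",
    "track_sequence",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegistrationConfig:
    """Tuning knobs of the tracking pipeline (all deterministic)."""

    tol: float = 1e-4
    max_iterations: int = 50
    patience: int = 5
    vertical_filter_deg: float = DEFAULT_VERTICAL_FILTER_DEG
    condyle_weight: float = DEFAULT_CONDYLE_WEIGHT
    middle_slice_weight: float = DEFAULT_MIDDLE_SLICE_WEIGHT
    scale_bounds: tuple = (0.8, 1.25)
    icr_min_rotation_deg: float = DEFAULT_ICR_MIN_ROTATION_DEG
    normal_neighborhood: int = 1


@dataclass
class Pairing:
    """Per model point: nearest observed-point index, 3D offset and distance."""

    indices: np.ndarray
    offsets: np.ndarray
    distances: np.ndarray


@dataclass
class FrameRegistration:
    """Result of registering one frame against the first-frame model."""

    transform: ScaledTransform2D
    superimposition_error: float
    n_iterations: int
    converged: bool
    frame: int | None = None


@dataclass
class TrackingResult:
    """Per-frame registrations plus the model cloud and provenance metadata."""

    frames: list
    model: PointCloud
    params: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def transforms(self) -> list:
        return [f.transform for f in self.frames]

    @property
    def errors(self) -> np.ndarray:
        return np.array([f.superimposition_error for f in self.frames])

    @property
    def converged(self) -> np.ndarray:
        return np.array([f.converged for f in self.frames])


def lifted_apply(t, xyz: np.ndarray) -> np.ndarray:
    """Apply a planar transform to the (x, y) part of lifted points; z unchanged."""
    out = np.array(xyz, dtype=float, copy=True)
    out[:, :2] = t.apply(xyz[:, :2])
    return out


def pair_points(points: np.ndarray, observed: PointCloud) -> Pairing:
    """Pair each (transformed model) point with its nearest observed point in 3D.

    Correctness is defined by exhaustive search; a k-d tree is used as an
    equivalent optimization.  Exact distance ties resolve to the lowest
    observed-point index.
    """
    if len(observed) == 0:
        raise EmptyMaskError("observed cloud is empty")
    pts = np.asarray(points, dtype=float)
    dist, idx = cKDTree(observed.xyz).query(pts)
    offsets = pts - observed.xyz[idx]
    return Pairing(indices=idx.astype(np.intp), offsets=offsets, distances=dist)


def superimposition_error(points: np.ndarray, normals: np.ndarray, observed: PointCloud, pairing: Pairing) -> float:
    """Unweighted mean of |normal · (model point − paired observed point)|."""
    q = observed.xyz[pairing.indices]
    proj = np.einsum("ij,ij->i", normals, np.asarray(points) - q)
    return float(np.mean(np.abs(proj)))


def _weighted_lstsq(a: np.ndarray, b: np.ndarray, w: np.ndarray, min_rank: int):
    sw = np.sqrt(w)[:, None]
    sol, _, rank, _ = np.linalg.lstsq(a * sw, b * sw[:, 0], rcond=None)
    if rank < min_rank:
        raise DegenerateGeometryError(
            f"normal-equation system is rank deficient ({rank} < {min_rank})"
        )
    return sol


def fit_rigid_point_to_plane(
    pairing: Pairing,
    model: PointCloud,
    observed: PointCloud,
    weights: np.ndarray | None = None,
    h: tuple = (1.0, 1.0),
    theta0: float = 0.0,
    inner_tol: float = 1e-10,
    max_inner: int = 30,
) -> RigidTransform2D:
    """Weighted point-to-plane rigid fit.

    Minimizes ``sum_i w_i [n_i · (R(theta) H x_i + T − q_i)]^2`` over
    ``(theta, T)`` by iterated small-angle (Gauss-Newton) linearization until
    the objective decreases by less than ``inner_tol``.  ``H`` is held fixed.
    """
    if model.normals is None:
        raise InvalidInputError("model normals are required")
    if len(model) < 3:
        raise InsufficientDataError("need >= 3 pairs")
    n = model.normals
    xh = model.xyz[:, :2] * np.asarray(h, dtype=float)
    z = model.xyz[:, 2]
    q = observed.xyz[pairing.indices]
    w = np.ones(len(model)) if weights is None else np.asarray(weights, dtype=float)
    # residual r = nxy·(R xh) + nx Tx + ny Ty + const
    const = n[:, 2] * z - np.einsum("ij,ij->i", n, q)

    theta = float(theta0)
    t = np.zeros(2)

    def objective(th, tt):
        rx = xh @ rotation_matrix(th).T
        r = np.einsum("ij,ij->i", n[:, :2], rx) + n[:, 0] * tt[0] + n[:, 1] * tt[1] + const
        return float(np.sum(w * r * r)), r

    obj, r = objective(theta, t)
    for it in range(max_inner):
        rx = xh @ rotation_matrix(theta).T
        drx = xh @ rotation_matrix(theta + np.pi / 2.0).T  # d(Rx)/dtheta
        jac = np.column_stack(
            [np.einsum("ij,ij->i", n[:, :2], drx), n[:, 0], n[:, 1]]
        )
        step = _weighted_lstsq(jac, -r, w, min_rank=3)
        theta_new = theta + step[0]
        t_new = t + step[1:]
        obj_new, r_new = objective(theta_new, t_new)
        if obj_new > obj:  # damped fallback for an overshooting Newton step
            alpha = 0.5
            while alpha > 1e-4 and obj_new > obj:
                theta_new = theta + alpha * step[0]
                t_new = t + alpha * step[1:]
                obj_new, r_new = objective(theta_new, t_new)
                alpha *= 0.5
            if obj_new > obj:
                break
        decrease = obj - obj_new
        theta, t, obj, r = theta_new, t_new, obj_new, r_new
        if decrease < inner_tol * max(1.0, obj):
            break
    return RigidTransform2D(theta, t[0], t[1])


def fit_scaling(
    pairing: Pairing,
    model: PointCloud,
    observed: PointCloud,
    theta: float,
    weights: np.ndarray | None = None,
    bounds: tuple = (0.8, 1.25),
) -> ScaledTransform2D:
    """Joint linear fit of the homothety ``H = diag(h11, h22)`` and translation.

    With the rotation fixed, the projected residual is linear in
    ``(h11, h22, Tx, Ty)``; solved by weighted least squares, with the scale
    factors clamped to ``bounds`` (translation re-solved after clamping).
    """
    if model.normals is None:
        raise InvalidInputError("model normals are required")
    if len(model) < 4:
        raise InsufficientDataError("need >= 4 pairs")
    n = model.normals
    x = model.xyz[:, :2]
    z = model.xyz[:, 2]
    q = observed.xyz[pairing.indices]
    w = np.ones(len(model)) if weights is None else np.asarray(weights, dtype=float)
    rot = rotation_matrix(theta)
    # nxy·(R H x) = h11 * x * (nxy·Rcol1) + h22 * y * (nxy·Rcol2)
    a1 = x[:, 0] * (n[:, :2] @ rot[:, 0])
    a2 = x[:, 1] * (n[:, :2] @ rot[:, 1])
    design = np.column_stack([a1, a2, n[:, 0], n[:, 1]])
    b = np.einsum("ij,ij->i", n, q) - n[:, 2] * z
    sol = _weighted_lstsq(design, b, w, min_rank=4)
    h11 = float(np.clip(sol[0], *bounds))
    h22 = float(np.clip(sol[1], *bounds))
    if h11 != sol[0] or h22 != sol[1]:
        # re-solve translation with the clamped homothety held fixed
        b2 = b - h11 * a1 - h22 * a2
        t = _weighted_lstsq(np.column_stack([n[:, 0], n[:, 1]]), b2, w, min_rank=2)
    else:
        t = sol[2:]
    return ScaledTransform2D(theta, float(t[0]), float(t[1]), h11, h22)


def register_frame(
    model: PointCloud,
    observed: PointCloud,
    init: RigidTransform2D | ScaledTransform2D,
    config: RegistrationConfig | None = None,
) -> FrameRegistration:
    """Iterated pair → rigid fit → scaling fit until the superimposition error
    stabilizes.

    Only cycles that do not increase the error are *accepted* (the accepted
    error series is non-increasing and the best state is what is returned);
    the search itself is allowed to pass through up to ``config.patience``
    consecutive error-increasing cycles, because the optimizer minimizes the
    weighted squared projected distance while the reported error is the
    unweighted mean absolute one — small transient upticks are normal.
    Terminates when an accepted cycle improves the error by less than ``tol``
    (relative), when patience runs out, or at ``max_iterations``.
    """
    config = config or RegistrationConfig()
    t = init if isinstance(init, ScaledTransform2D) else ScaledTransform2D.from_rigid(init)
    p = lifted_apply(t, model.xyz)
    pairing = pair_points(p, observed)
    best_t, best_err, n_it = t, superimposition_error(p, model.normals, observed, pairing), 0
    stall = 0
    for it in range(1, config.max_iterations + 1):
        rigid = fit_rigid_point_to_plane(
            pairing, model, observed, model.weights, h=(t.h11, t.h22), theta0=t.theta
        )
        t_new = fit_scaling(
            pairing, model, observed, rigid.theta, model.weights, config.scale_bounds
        )
        p = lifted_apply(t_new, model.xyz)
        pairing = pair_points(p, observed)
        err = superimposition_error(p, model.normals, observed, pairing)
        t = t_new  # search continues from the new state either way
        if err <= best_err + 1e-12 * max(1.0, best_err):
            improvement = (best_err - err) / max(best_err, 1e-12)
            best_t, best_err, n_it = t_new, min(err, best_err), it
            stall = 0
            if improvement < config.tol:
                return FrameRegistration(best_t, best_err, n_it, True)
        else:
            stall += 1
            if stall >= config.patience:
                return FrameRegistration(best_t, best_err, it, True)
    return FrameRegistration(best_t, best_err, config.max_iterations, False)


def build_model_cloud(frames, annotation: StudyAnnotation, config: RegistrationConfig | None = None):
    """First-frame model cloud (all slices pooled) and per-slice normalization.

    Returns ``(cloud, params)`` with ``params`` mapping slice id to
    :class:`NormalizationParams` computed from that slice's first frame.
    """
    config = config or RegistrationConfig()
    spacing = frames.pixel_spacing
    shape = frames.data.shape[2:]
    params: dict[int, NormalizationParams] = {}
    parts = []
    for area in annotation.slices:
        sid = area.slice_id
        mask = rasterize_polygon(area.mandible_polygon, shape, spacing)
        img = frames.data[0, sid - 1]
        rows, cols = np.nonzero(mask)
        coords = np.column_stack([cols * spacing[0], rows * spacing[1]])
        params[sid] = compute_intensity_scale(coords, img[rows, cols])
        parts.append(lift_to_cloud(mask, img, sid, params[sid], spacing))
    cloud = PointCloud.concatenate(parts)
    cloud = estimate_normals(cloud, config.normal_neighborhood)
    cloud = filter_near_vertical(cloud, config.vertical_filter_deg)
    cloud = assign_weights(
        cloud,
        annotation.slices,
        annotation.middle_slice_id,
        config.condyle_weight,
        config.middle_slice_weight,
    )
    return cloud, params


def extract_observed_cloud(
    frames,
    annotation: StudyAnnotation,
    frame: int,
    mask_transform,
    params: dict,
    config: RegistrationConfig | None = None,
) -> PointCloud:
    """Observed cloud of one frame, masked by the transformed first-frame area.

    The first-frame mandible polygon of each slice is mapped through
    ``mask_transform`` (the rough transform during tracking) and rasterized;
    the covered pixels are lifted with that slice's first-frame normalization.
    """
    config = config or RegistrationConfig()
    spacing = frames.pixel_spacing
    shape = frames.data.shape[2:]
    parts = []
    for area in annotation.slices:
        sid = area.slice_id
        poly = mask_transform.apply(area.mandible_polygon)
        try:
            mask = rasterize_polygon(poly, shape, spacing)
        except EmptyMaskError:
            continue
        img = frames.data[frame - 1, sid - 1]
        parts.append(lift_to_cloud(mask, img, sid, params[sid], spacing))
    if not parts:
        raise EmptyMaskError(f"frame {frame}: transformed area covers no pixels")
    cloud = PointCloud.concatenate(parts)
    cloud = estimate_normals(cloud, config.normal_neighborhood)
    cloud = filter_near_vertical(cloud, config.vertical_filter_deg)
    return cloud


def rough_transform(annotation: StudyAnnotation, frame: int) -> RigidTransform2D:
    """SVD rigid fit of the three mandibular landmarks, frame 1 → ``frame``.

    Landmarks are linearly interpolated between the bracketing keyframes; the
    two temporal-bone landmarks are static anatomy and deliberately excluded.
    """
    lm1 = interpolate_landmarks(annotation.keyframes, 1).array(MANDIBULAR_LANDMARKS)
    lmf = interpolate_landmarks(annotation.keyframes, frame).array(MANDIBULAR_LANDMARKS)
    return fit_rigid_svd(lm1, lmf)


def error_series(transforms, model: PointCloud, observed_clouds) -> np.ndarray:
    """Superimposition error of given transforms against per-frame observed clouds."""
    errors = np.full(len(transforms), np.nan)
    for i, (t, obs) in enumerate(zip(transforms, observed_clouds)):
        if obs is None or len(obs) == 0:
            continue
        p = lifted_apply(t, model.xyz)
        pairing = pair_points(p, obs)
        errors[i] = superimposition_error(p, model.normals, obs, pairing)
    return errors


def track_sequence(frames, annotation: StudyAnnotation, config: RegistrationConfig | None = None) -> TrackingResult:
    """Track the whole sequence against the first-frame model.

    Per frame: interpolate landmarks, fit the rough rigid transform, mask the
    frame through it, extract the observed cloud and run the LMS registration
    initialized at the rough transform.  Frames whose mask is empty (or whose
    grey spread degenerates) are recorded as failed and tracking continues.
    """
    config = config or RegistrationConfig()
    model, params = build_model_cloud(frames, annotation, config)
    results = []
    for f in range(1, frames.n_frames + 1):
        rough = rough_transform(annotation, f)
        try:
            observed = extract_observed_cloud(frames, annotation, f, rough, params, config)
            reg = register_frame(model, observed, rough, config)
        except (EmptyMaskError, ZeroSpreadError, DegenerateGeometryError) as exc:
            logger.warning("frame %d failed: %s", f, exc)
            reg = FrameRegistration(ScaledTransform2D.from_rigid(rough), float("nan"), 0, False)
        reg.frame = f
        logger.info(
            "frame %d: %d iterations, error %.6f", f, reg.n_iterations, reg.superimposition_error
        )
        results.append(reg)
    return TrackingResult(
        frames=results,
        model=model,
        params=params,
        meta={"n_frames": frames.n_frames, "n_slices": annotation.n_slices},
    )
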
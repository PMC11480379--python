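"""Planar transforms, landmark-based rigid fitting, Pratt circle fitting and the
instantaneous center of rotation.

Angle convention
----------------
``theta`` is counterclockwise-positive in the image frame with
``x = column * spacing`` pointing right, ``y = row * spacing`` pointing down and
the origin at the center of the top-left pixel.  The rotation matrix is::

    R(theta) = [[cos, -sin],
                [sin,  cos]]

Transforms compose as scale-then-rotate-then-translate: ``y = T + R @ H @ x``.
All lengths are millimetres; angles are radians unless a name says ``deg``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg

from .exceptions import DegenerateConfigurationError, InvalidInputError

__all__ = [
    "RigidTransform2D",
    "ScaledTransform2D",
    "CircleFit",
    "rotation_matrix",
    "apply_transform",
    "fit_rigid_svd",
    "fit_circle_pratt",
    "compute_icr",
]

DEFAULT_ICR_MIN_ROTATION_DEG = 0.1


def rotation_matrix(theta: float) -> np.ndarray:
    """2x2 counterclockwise rotation matrix for angle ``theta`` (radians)."""
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(1, -1)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError(f"expected (n, 2) points, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise InvalidInputError("points contain non-finite values")
    return pts


@dataclass(frozen=True)
class RigidTransform2D:
    """Planar rigid map ``y = T + R(theta) @ x``."""

    theta: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls(0.0, 0.0, 0.0)

    @property
    def rotation(self) -> np.ndarray:
        return rotation_matrix(self.theta)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty])

    def apply(self, points) -> np.ndarray:
        pts = _as_points(points)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Return ``self ∘ other`` (``other`` applied first)."""
        t = self.translation + self.rotation @ other.translation
        return RigidTransform2D(self.theta + other.theta, t[0], t[1])

    def inverse(self) -> "RigidTransform2D":
        rinv = rotation_matrix(-self.theta)
        t = -(rinv @ self.translation)
        return RigidTransform2D(-self.theta, t[0], t[1])

    def as_scaled(self) -> "ScaledTransform2D":
        return ScaledTransform2D(self.theta, self.tx, self.ty, 1.0, 1.0)


@dataclass(frozen=True)
class ScaledTransform2D:
    """Planar map ``y = T + R(theta) @ diag(h11, h22) @ x``.

    With ``h11 == h22 == 1`` this is exactly a :class:`RigidTransform2D`.
    """

    theta: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    h11: float = 1.0
    h22: float = 1.0

    def __post_init__(self):
        if not (self.h11 > 0 and self.h22 > 0):
            raise InvalidInputError("scaling factors must be positive")

    @classmethod
    def identity(cls) -> "ScaledTransform2D":
        return cls()

    @classmethod
    def from_rigid(cls, rigid: RigidTransform2D) -> "ScaledTransform2D":
        return cls(rigid.theta, rigid.tx, rigid.ty, 1.0, 1.0)

    @property
    def rotation(self) -> np.ndarray:
        return rotation_matrix(self.theta)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty])

    @property
    def scaling(self) -> np.ndarray:
        return np.diag([self.h11, self.h22])

    def rigid_part(self) -> RigidTransform2D:
        return RigidTransform2D(self.theta, self.tx, self.ty)

    def apply(self, points) -> np.ndarray:
        pts = _as_points(points)
        scaled = pts * np.array([self.h11, self.h22])
        return scaled @ self.rotation.T + self.translation

    def with_rigid(self, rigid: RigidTransform2D) -> "ScaledTransform2D":
        return replace(self, theta=rigid.theta, tx=rigid.tx, ty=rigid.ty)


@dataclass(frozen=True)
class CircleFit:
    """Circle ``(cx, cy, r)`` with the RMS radial residual of the fit."""

    cx: float
    cy: float
    r: float
    rms: float

    @property
    def center(self) -> np.ndarray:
        return np.array([self.cx, self.cy])


def apply_transform(t, points) -> np.ndarray:
    """Apply a rigid or scaled planar transform to ``(n, 2)`` points."""
    return t.apply(points)


def fit_rigid_svd(src, dst) -> RigidTransform2D:
    """Least-squares rigid transform mapping ``src`` onto ``dst``.

    Minimizes ``sum_i || T + R @ src_i - dst_i ||^2`` (Kabsch / Procrustes via
    SVD with the determinant correction); exact whenever ``dst`` is a rigid
    image of ``src``.
    """
    s = _as_points(src)
    d = _as_points(dst)
    if s.shape != d.shape:
        raise InvalidInputError("src and dst must have the same shape")
    if len(s) < 2:
        raise DegenerateConfigurationError("need at least 2 landmark pairs")
    cs, cd = s.mean(axis=0), d.mean(axis=0)
    s0, d0 = s - cs, d - cd
    if np.max(np.abs(s0)) < 1e-12:
        raise DegenerateConfigurationError("all source points coincide")
    h = s0.T @ d0
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, sign if sign != 0 else 1.0]) @ u.T
    theta = math.atan2(r[1, 0], r[0, 0])
    t = cd - rotation_matrix(theta) @ cs
    return RigidTransform2D(theta, t[0], t[1])


def fit_circle_pratt(points) -> CircleFit:
    """Pratt's algebraic least-squares circle fit.

    Solves the generalized eigenproblem for ``A(x^2+y^2) + Bx + Cy + D = 0``
    under the constraint ``B^2 + C^2 - 4AD = 1``; exact on points lying on a
    circle.
    """
    pts = _as_points(points)
    if len(pts) < 3:
        raise DegenerateConfigurationError("need at least 3 points")
    centroid = pts.mean(axis=0)
    xy = pts - centroid
    # collinearity check on centered coordinates
    _, svals, _ = np.linalg.svd(xy, full_matrices=False)
    if svals[-1] < 1e-9 * max(svals[0], 1.0):
        raise DegenerateConfigurationError("points are collinear")
    x, y = xy[:, 0], xy[:, 1]
    z = x * x + y * y
    design = np.column_stack([z, x, y, np.ones_like(x)])
    m = design.T @ design / len(pts)
    constraint = np.array(
        [
            [0.0, 0.0, 0.0, -2.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [-2.0, 0.0, 0.0, 0.0],
        ]
    )
    eigvals, eigvecs = scipy.linalg.eig(m, constraint)
    eigvals = np.real(eigvals)
    finite = np.isfinite(eigvals)
    # smallest non-negative eigenvalue (tolerate tiny negative round-off)
    candidates = np.where(finite & (eigvals > -1e-10))[0]
    if len(candidates) == 0:
        raise DegenerateConfigurationError("circle fit eigenproblem degenerate")
    best = candidates[np.argmin(eigvals[candidates])]
    a, b, c, d = np.real(eigvecs[:, best])
    if abs(a) < 1e-14:
        raise DegenerateConfigurationError("fit degenerates to a line")
    cx = -b / (2.0 * a)
    cy = -c / (2.0 * a)
    disc = b * b + c * c - 4.0 * a * d
    if disc <= 0:
        raise DegenerateConfigurationError("fit has non-positive radius")
    r = math.sqrt(disc) / (2.0 * abs(a))
    center = np.array([cx, cy]) + centroid
    dist = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    rms = float(np.sqrt(np.mean((dist - r) ** 2)))
    return CircleFit(float(center[0]), float(center[1]), float(r), rms)


def compute_icr(t_prev, t_curr, min_rotation_deg: float = DEFAULT_ICR_MIN_ROTATION_DEG):
    """Instantaneous center of rotation of the step ``t_prev -> t_curr``.

    Uses the rigid parts only.  With ``delta = t_curr ∘ t_prev^-1``, returns the
    fixed point ``c`` solving ``c = R_delta @ c + T_delta`` when
    ``|delta.theta| >= min_rotation_deg``; otherwise ``None`` ("undefined",
    near-singular ``I - R`` inversion).
    """
    prev = t_prev.rigid_part() if hasattr(t_prev, "rigid_part") else t_prev
    curr = t_curr.rigid_part() if hasattr(t_curr, "rigid_part") else t_curr
    delta = curr.compose(prev.inverse())
    if abs(delta.theta) < math.radians(min_rotation_deg):
        return None
    lhs = np.eye(2) - delta.rotation
    c = np.linalg.solve(lhs, delta.translation)
    return c
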
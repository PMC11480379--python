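"""Turn masked mandible pixels into a weighted, oriented 3D point cloud.

The grey value of each masked pixel is lifted to a third spatial coordinate so
intensity and space share units: the first frame fixes a scale relating the
grey interdecile spread to the spatial spread along the shape's minor axis, and
every later frame has its grey distribution affinely matched onto the first
frame's decile range before lifting.  Per-point surface normals come from a
local PCA of the lifted lattice neighborhood; near-vertical normals (flat
intensity) are filtered out, and points are weighted by anatomical importance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .annotation import AreaAnnotation, points_in_polygon
from .exceptions import (
    EmptyMaskError,
    InsufficientDataError,
    InvalidInputError,
    ZeroSpreadError,
)

__all__ = [
    "NormalizationParams",
    "PointCloud",
    "interdecile",
    "compute_intensity_scale",
    "match_grey_distribution",
    "lift_to_cloud",
    "estimate_normals",
    "filter_near_vertical",
    "assign_weights",
]

#: Denominator factor tying grey spread to 1/8 of the minor-axis spatial spread.
INTENSITY_SCALE_DIVISOR = 8.0
DEFAULT_VERTICAL_FILTER_DEG = 8.0
DEFAULT_CONDYLE_WEIGHT = 2.0
DEFAULT_MIDDLE_SLICE_WEIGHT = 2.5


def interdecile(values) -> float:
    """Spread between the 10th and 90th percentile (linear interpolation)."""
    v = np.asarray(values, dtype=float)
    lo, hi = np.percentile(v, [10.0, 90.0])
    return float(hi - lo)


@dataclass(frozen=True)
class NormalizationParams:
    """First-frame grey normalization: intensity-lift scale and decile anchors."""

    scale_first: float
    d1_first: float
    interdecile_first: float

    def __post_init__(self):
        if not (self.scale_first > 0 and self.interdecile_first > 0):
            raise InvalidInputError("normalization parameters must be positive")


@dataclass
class PointCloud:
    """Lifted pixels of one or several slices.

    ``xyz`` is ``(n, 3)`` in mm (z = lifted grey); ``rows``/``cols`` keep the
    originating lattice position for neighborhood queries.  ``normals``,
    ``weights`` and ``is_condyle`` are filled by the pipeline stages.
    """

    xyz: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    slice_ids: np.ndarray
    normals: np.ndarray | None = None
    weights: np.ndarray | None = None
    is_condyle: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.xyz)

    def subset(self, keep: np.ndarray) -> "PointCloud":
        return PointCloud(
            xyz=self.xyz[keep],
            rows=self.rows[keep],
            cols=self.cols[keep],
            slice_ids=self.slice_ids[keep],
            normals=None if self.normals is None else self.normals[keep],
            weights=None if self.weights is None else self.weights[keep],
            is_condyle=None if self.is_condyle is None else self.is_condyle[keep],
        )

    @staticmethod
    def concatenate(clouds) -> "PointCloud":
        def cat(attr):
            parts = [getattr(c, attr) for c in clouds]
            return None if any(p is None for p in parts) else np.concatenate(parts)

        return PointCloud(
            xyz=np.concatenate([c.xyz for c in clouds]),
            rows=np.concatenate([c.rows for c in clouds]),
            cols=np.concatenate([c.cols for c in clouds]),
            slice_ids=np.concatenate([c.slice_ids for c in clouds]),
            normals=cat("normals"),
            weights=cat("weights"),
            is_condyle=cat("is_condyle"),
        )


def compute_intensity_scale(coords, greys) -> NormalizationParams:
    """Normalization parameters from the first frame's masked pixels.

    The lift scale is ``interdecile(projection of coords onto the
    least-variance principal axis) / (8 * interdecile(greys))``.
    """
    c = np.asarray(coords, dtype=float)
    g = np.asarray(greys, dtype=float)
    if len(c) < 10:
        raise InsufficientDataError(f"need >= 10 pixels, got {len(c)}")
    spread_g = interdecile(g)
    if spread_g <= 0:
        raise ZeroSpreadError("grey values have zero interdecile spread")
    centered = c - c.mean(axis=0)
    cov = centered.T @ centered / len(c)
    _, vecs = np.linalg.eigh(cov)
    minor_axis = vecs[:, 0]  # eigh sorts ascending: least-variance axis first
    proj = c @ minor_axis
    spread_p = interdecile(proj)
    if spread_p <= 0:
        raise ZeroSpreadError("coordinates have zero spread along the minor axis")
    scale = spread_p / (INTENSITY_SCALE_DIVISOR * spread_g)
    d1 = float(np.percentile(g, 10.0))
    return NormalizationParams(scale_first=scale, d1_first=d1, interdecile_first=spread_g)


def match_grey_distribution(greys_curr, params: NormalizationParams, d1_curr: float, interdecile_curr: float) -> np.ndarray:
    """Affine map sending the current frame's decile range onto the first frame's."""
    if interdecile_curr <= 0:
        raise ZeroSpreadError("current frame grey values have zero interdecile spread")
    g = np.asarray(greys_curr, dtype=float)
    return (g - d1_curr) * (params.interdecile_first / interdecile_curr) + params.d1_first


def lift_to_cloud(mask, image, slice_id: int, params: NormalizationParams, pixel_spacing) -> PointCloud:
    """One point per masked pixel, grey distribution matched then lifted to z."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("mask contains no pixels")
    img = np.asarray(image, dtype=float)
    rows, cols = np.nonzero(mask)
    greys = img[rows, cols]
    d1_curr = float(np.percentile(greys, 10.0))
    spread_curr = interdecile(greys)
    matched = match_grey_distribution(greys, params, d1_curr, spread_curr)
    sx, sy = float(pixel_spacing[0]), float(pixel_spacing[1])
    xyz = np.column_stack([cols * sx, rows * sy, params.scale_first * matched])
    return PointCloud(
        xyz=xyz,
        rows=rows.astype(np.intp),
        cols=cols.astype(np.intp),
        slice_ids=np.full(len(rows), slice_id, dtype=np.intp),
        is_condyle=np.zeros(len(rows), dtype=bool),
    )


def _neighbor_indices(cloud: PointCloud, radius: int) -> np.ndarray:
    """Index of each lattice neighbor per point, ``-1`` where absent.

    Neighborhood is the ``(2*radius+1)^2`` window minus the center, within the
    same slice.
    """
    n = len(cloud)
    offsets = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if (dr, dc) != (0, 0)
    ]
    neigh = np.full((n, len(offsets)), -1, dtype=np.intp)
    for sid in np.unique(cloud.slice_ids):
        sel = np.nonzero(cloud.slice_ids == sid)[0]
        r, c = cloud.rows[sel], cloud.cols[sel]
        r0, c0 = r.min(), c.min()
        grid = np.full((r.max() - r0 + 1 + 2 * radius, c.max() - c0 + 1 + 2 * radius), -1, dtype=np.intp)
        grid[r - r0 + radius, c - c0 + radius] = sel
        for k, (dr, dc) in enumerate(offsets):
            neigh[sel, k] = grid[r - r0 + radius + dr, c - c0 + radius + dc]
    return neigh


def estimate_normals(cloud: PointCloud, neighborhood: int = 1) -> PointCloud:
    """Per-point unit normal from PCA of the point and its lattice neighbors.

    The normal is the least-variance principal axis of the lifted 3D positions
    of the point and its in-slice lattice neighbors, sign-fixed so the z
    component is non-negative.  Points with fewer than 3 neighbors are dropped.
    """
    n = len(cloud)
    if n == 0:
        raise EmptyMaskError("empty cloud")
    neigh = _neighbor_indices(cloud, neighborhood)
    valid = neigh >= 0
    counts = valid.sum(axis=1)
    keep = counts >= 3

    # batched covariance of {point} ∪ neighbors, invalid slots masked to zero
    safe = np.where(valid, neigh, 0)
    pos = cloud.xyz[safe]  # (n, k, 3)
    w = valid[:, :, None].astype(float)
    mean = ((pos * w).sum(axis=1) + cloud.xyz) / (counts[:, None] + 1.0)
    d_self = cloud.xyz - mean
    d_neigh = (pos - mean[:, None, :]) * w  # w in {0,1}: masks invalid rows
    cov = np.einsum("nki,nkj->nij", d_neigh, d_neigh)
    cov += np.einsum("ni,nj->nij", d_self, d_self)
    cov /= (counts[:, None, None] + 1.0)

    kept = np.nonzero(keep)[0]
    _, vecs = np.linalg.eigh(cov[kept])
    normals = vecs[:, :, 0]  # least-variance axis
    # deterministic sign: z >= 0, tie-broken by x then y
    flip = (normals[:, 2] < 0) | (
        (normals[:, 2] == 0) & ((normals[:, 0] < 0) | ((normals[:, 0] == 0) & (normals[:, 1] < 0)))
    )
    normals[flip] *= -1.0

    out = cloud.subset(keep)
    out.normals = normals
    return out


def filter_near_vertical(cloud: PointCloud, threshold_deg: float = DEFAULT_VERTICAL_FILTER_DEG) -> PointCloud:
    """Drop points whose normal is closer than ``threshold_deg`` to vertical.

    The boundary angle (exactly ``threshold_deg``) is retained.
    """
    if cloud.normals is None:
        raise InvalidInputError("normals must be estimated before filtering")
    nx, ny, nz = cloud.normals.T
    angle = np.degrees(np.arctan2(np.hypot(nx, ny), np.abs(nz)))
    keep = angle >= threshold_deg - 1e-9
    return cloud.subset(keep)


def assign_weights(
    cloud: PointCloud,
    condyle_regions,
    middle_slice_id: int,
    condyle_factor: float = DEFAULT_CONDYLE_WEIGHT,
    middle_factor: float = DEFAULT_MIDDLE_SLICE_WEIGHT,
) -> PointCloud:
    """Weight points by anatomical importance.

    ``weight = 1 * condyle_factor (inside the condyle contour)
    * middle_factor (on the TMJ-centered middle slice)`` — {1, 2, 2.5, 5} with
    the defaults.  ``condyle_regions`` maps slice id -> :class:`AreaAnnotation`
    (or is an iterable of them); the condyle contour is closed implicitly.
    """
    if isinstance(condyle_regions, dict):
        regions = condyle_regions
    else:
        regions = {a.slice_id: a for a in condyle_regions}
    weights = np.ones(len(cloud))
    is_condyle = np.zeros(len(cloud), dtype=bool)
    for sid, area in regions.items():
        sel = cloud.slice_ids == sid
        if not sel.any() or len(area.condyle_contour) < 3:
            continue
        inside = points_in_polygon(cloud.xyz[sel, :2], area.condyle_contour)
        idx = np.nonzero(sel)[0][inside]
        is_condyle[idx] = True
    weights[is_condyle] *= condyle_factor
    weights[cloud.slice_ids == middle_slice_id] *= middle_factor
    out = replace(cloud)
    out.weights = weights
    out.is_condyle = is_condyle
    return out
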
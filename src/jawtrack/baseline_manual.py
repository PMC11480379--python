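"""Manual two-landmark tracking baseline.

Per frame, the rater places the condylar superior point and the gonion; the
translation follows the condylar superior point and the rotation is adjusted
from the gonion direction.  The resulting rigid transform maps first-frame
points to the current frame, sending both defining landmarks exactly onto
their current positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateConfigurationError, EmptyMaskError, ZeroSpreadError
from .extraction import PointCloud
from .geometry2d import RigidTransform2D, rotation_matrix
from .registration import (
    RegistrationConfig,
    extract_observed_cloud,
    lifted_apply,
    pair_points,
    superimposition_error,
)

__all__ = [
    "LANDMARKS_PER_FRAME",
    "ManualFrameLandmarks",
    "manual_track_frame",
    "manual_track_sequence",
    "manual_error_series",
]

#: The manual protocol places exactly two landmarks on every frame.
LANDMARKS_PER_FRAME = 2


@dataclass(frozen=True)
class ManualFrameLandmarks:
    """Two manual landmarks of one frame, in mm."""

    condyle_superior: np.ndarray
    gonion: np.ndarray
    frame: int = 1

    def __post_init__(self):
        object.__setattr__(self, "condyle_superior", np.asarray(self.condyle_superior, dtype=float))
        object.__setattr__(self, "gonion", np.asarray(self.gonion, dtype=float))
        if np.allclose(self.condyle_superior, self.gonion):
            raise DegenerateConfigurationError("condyle superior and gonion coincide")


def manual_track_frame(first: ManualFrameLandmarks, current: ManualFrameLandmarks) -> RigidTransform2D:
    """Rigid transform from the two manual landmarks.

    Translation follows the condylar superior point; rotation is the signed
    angle between the condyle→gonion directions, applied about the current
    condylar superior position.  Both landmarks are mapped exactly.
    """
    v0 = first.gonion - first.condyle_superior
    v1 = current.gonion - current.condyle_superior
    theta = math.atan2(
        v0[0] * v1[1] - v0[1] * v1[0],  # cross
        float(v0 @ v1),  # dot
    )
    t = current.condyle_superior - rotation_matrix(theta) @ first.condyle_superior
    return RigidTransform2D(theta, float(t[0]), float(t[1]))


def manual_track_sequence(landmarks) -> list:
    """Per-frame transforms from a table of manual landmarks.

    ``landmarks`` is a pandas DataFrame (or equivalent mapping of columns)
    with columns ``frame, cs_x, cs_y, go_x, go_y`` in mm, one row per frame in
    order; the first row is the reference.
    """
    frames = np.asarray(landmarks["frame"], dtype=int)
    cs = np.column_stack([np.asarray(landmarks["cs_x"], float), np.asarray(landmarks["cs_y"], float)])
    go = np.column_stack([np.asarray(landmarks["go_x"], float), np.asarray(landmarks["go_y"], float)])
    first = ManualFrameLandmarks(cs[0], go[0], int(frames[0]))
    out = []
    for i in range(len(frames)):
        curr = ManualFrameLandmarks(cs[i], go[i], int(frames[i]))
        out.append(manual_track_frame(first, curr))
    return out


def manual_error_series(
    transforms,
    model: PointCloud,
    frames,
    annotation,
    params: dict,
    config: RegistrationConfig | None = None,
) -> np.ndarray:
    """Superimposition error of the manual transforms, frame by frame.

    Applies each manual transform to the model cloud and evaluates the same
    superimposition-error operation used by automatic tracking, with pairing
    recomputed per frame.  The observed cloud of each frame is masked by the
    manual transform itself (the manual method has no rough transform).
    """
    config = config or RegistrationConfig()
    errors = np.full(len(transforms), np.nan)
    for i, t in enumerate(transforms):
        try:
            observed = extract_observed_cloud(frames, annotation, i + 1, t, params, config)
        except (EmptyMaskError, ZeroSpreadError):
            continue
        p = lifted_apply(t, model.xyz)
        pairing = pair_points(p, observed)
        errors[i] = superimposition_error(p, model.normals, observed, pairing)
    return errors
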
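"""Readers and writers: image sequences (multi-page TIFF per slice or 4D
NIfTI), annotation JSON, landmark and result CSVs, configuration files."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    AreaAnnotation,
    KeyframeTrack,
    LandmarkSet,
    StudyAnnotation,
)
from .exceptions import (
    GeometryMismatchError,
    InvalidInputError,
    MalformedAnnotationError,
    MissingFileError,
)

__all__ = [
    "FrameSequence",
    "read_annotation",
    "write_annotation",
    "load_frames",
    "write_frames_tiff",
    "write_frames_nifti",
    "load_study",
    "save_results",
    "transforms_to_dataframe",
    "read_manual_landmarks",
    "write_manual_landmarks",
    "load_config",
]


@dataclasses.dataclass
class FrameSequence:
    """Grey values indexed ``(frame, slice, row, column)`` plus geometry."""

    data: np.ndarray
    pixel_spacing: tuple = (0.75, 0.75)
    frame_rate: float = 10.0
    slice_gap: float = 6.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise InvalidInputError("frame data must be 4D (frame, slice, row, col)")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise InvalidInputError("need at least one frame and one slice")
        if not (self.pixel_spacing[0] > 0 and self.pixel_spacing[1] > 0):
            raise InvalidInputError("pixel spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def image_shape(self) -> tuple:
        return self.data.shape[2:]


def read_annotation(path) -> StudyAnnotation:
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise MalformedAnnotationError(f"{path}: invalid JSON ({exc})") from exc
    try:
        slices = [
            AreaAnnotation(
                slice_id=int(s["slice_id"]),
                mandible_polygon=np.asarray(s["mandible_polygon"], dtype=float),
                condyle_contour=np.asarray(s["condyle_contour"], dtype=float),
                fossa_contour=np.asarray(s.get("fossa_contour", []), dtype=float).reshape(-1, 2),
            )
            for s in raw["slices"]
        ]
        sets = [LandmarkSet({k: np.asarray(v, float) for k, v in kf["landmarks"].items()}) for kf in raw["keyframes"]]
        track = KeyframeTrack([int(kf["frame"]) for kf in raw["keyframes"]], sets)
        return StudyAnnotation(
            pixel_spacing=tuple(raw["pixel_spacing_mm"]),
            n_frames=int(raw["n_frames"]),
            slices=slices,
            keyframes=track,
            cycle=tuple(raw["cycle"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, MalformedAnnotationError):
            raise
        raise MalformedAnnotationError(f"{path}: {exc}") from exc


def write_annotation(annotation: StudyAnnotation, path) -> None:
    payload = {
        "pixel_spacing_mm": list(annotation.pixel_spacing),
        "n_frames": annotation.n_frames,
        "slices": [
            {
                "slice_id": a.slice_id,
                "mandible_polygon": a.mandible_polygon.tolist(),
                "condyle_contour": a.condyle_contour.tolist(),
                "fossa_contour": a.fossa_contour.tolist(),
            }
            for a in annotation.slices
        ],
        "keyframes": [
            {"frame": f, "landmarks": {k: v.tolist() for k, v in s.points.items()}}
            for f, s in zip(annotation.keyframes.keyframe_indices, annotation.keyframes.landmark_sets)
        ],
        "cycle": list(annotation.cycle),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_frames_tiff(frames: FrameSequence, out_dir) -> list:
    """One multi-page TIFF per slice (pages = frames). Returns written paths."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in range(frames.n_slices):
        p = out_dir / f"slice_{s + 1:02d}.tif"
        tifffile.imwrite(p, frames.data[:, s].astype(np.float32))
        paths.append(p)
    return paths


def write_frames_nifti(frames: FrameSequence, path) -> Path:
    """4D NIfTI with axes (col, row, slice, frame); spacing in the header."""
    import nibabel as nib

    vol = np.transpose(frames.data, (3, 2, 1, 0)).astype(np.float32)
    affine = np.diag([frames.pixel_spacing[0], frames.pixel_spacing[1], frames.slice_gap, 1.0])
    img = nib.Nifti1Image(vol, affine)
    img.header["pixdim"][4] = 1.0 / frames.frame_rate if frames.frame_rate > 0 else 0.0
    nib.save(img, str(path))
    return Path(path)


def load_frames(image_paths, pixel_spacing=None, frame_rate: float = 10.0, slice_gap: float = 6.0) -> FrameSequence:
    """Load a sequence from per-slice multi-page TIFFs or a single 4D NIfTI."""
    if isinstance(image_paths, (str, Path)):
        image_paths = [image_paths]
    paths = [Path(p) for p in image_paths]
    for p in paths:
        if not p.exists():
            raise MissingFileError(str(p))
    if len(paths) == 1 and paths[0].suffix in {".nii", ".gz"}:
        import nibabel as nib

        img = nib.load(str(paths[0]))
        vol = np.asarray(img.dataobj)
        if vol.ndim == 3:
            vol = vol[:, :, :, None]
        data = np.transpose(vol, (3, 2, 1, 0))
        zooms = img.header.get_zooms()
        spacing = tuple(pixel_spacing) if pixel_spacing is not None else (float(zooms[0]), float(zooms[1]))
        gap = float(zooms[2]) if len(zooms) > 2 else slice_gap
        return FrameSequence(data, spacing, frame_rate, gap)
    import tifffile

    stacks = [tifffile.imread(p) for p in paths]
    shapes = {s.shape for s in stacks}
    if len(shapes) != 1:
        raise GeometryMismatchError(f"slices have differing shapes: {sorted(shapes)}")
    data = np.stack(stacks, axis=1)
    spacing = tuple(pixel_spacing) if pixel_spacing is not None else (0.75, 0.75)
    return FrameSequence(data, spacing, frame_rate, slice_gap)


def load_study(image_paths, annotation_path, pixel_spacing=None, frame_rate: float = 10.0, slice_gap: float = 6.0):
    """Load and cross-validate an image sequence with its annotation."""
    annotation = read_annotation(annotation_path)
    frames = load_frames(
        image_paths,
        pixel_spacing=pixel_spacing or annotation.pixel_spacing,
        frame_rate=frame_rate,
        slice_gap=slice_gap,
    )
    if frames.n_frames != annotation.n_frames:
        raise GeometryMismatchError(
            f"annotation declares {annotation.n_frames} frames, images have {frames.n_frames}"
        )
    if frames.n_slices != annotation.n_slices:
        raise GeometryMismatchError(
            f"annotation declares {annotation.n_slices} slices, images have {frames.n_slices}"
        )
    if tuple(frames.pixel_spacing) != tuple(annotation.pixel_spacing):
        raise GeometryMismatchError("pixel spacing mismatch between images and annotation")
    return frames, annotation


def transforms_to_dataframe(result) -> pd.DataFrame:
    """Transforms CSV layout: frame, tx_mm, ty_mm, theta_deg, h11, h22, error, iters, converged."""
    rows = []
    for i, fr in enumerate(result.frames, start=1):
        t = fr.transform
        rows.append(
            {
                "frame": fr.frame if fr.frame is not None else i,
                "tx_mm": t.tx,
                "ty_mm": t.ty,
                "theta_deg": np.degrees(t.theta),
                "h11": getattr(t, "h11", 1.0),
                "h22": getattr(t, "h22", 1.0),
                "superimposition_error": fr.superimposition_error,
                "n_iterations": fr.n_iterations,
                "converged": fr.converged,
            }
        )
    return pd.DataFrame(rows)


def save_results(result, report, out_dir) -> dict:
    """Write transforms CSV (always) and comparison JSON (when a report exists)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    df = transforms_to_dataframe(result)
    p = out_dir / "transforms.csv"
    df.to_csv(p, index=False)
    written["transforms"] = p
    if report is not None:
        p = out_dir / "comparison.json"
        p.write_text(json.dumps(report.to_dict(), indent=1))
        written["comparison"] = p
    return written


def write_manual_landmarks(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_manual_landmarks(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame", "cs_x", "cs_y", "go_x", "go_y"}
    if not required <= set(df.columns):
        raise MalformedAnnotationError(f"{path}: expected columns {sorted(required)}")
    return df


def load_config(path) -> dict:
    """Read a YAML or JSON configuration mapping."""
    import yaml

    path = Path(path)
    if not path.exists():
        raise MissingFileError(str(path))
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise MalformedAnnotationError(f"{path}: configuration must be a mapping")
    return data
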
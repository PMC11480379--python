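# jawtrack

Automatic and manual 2D tracking of mandibular motion in dynamic (real-time)
MRI image sequences.

The automatic method lifts the grey values of the annotated mandible area into
a third spatial coordinate, estimates per-pixel surface normals, and registers
this 3D representation frame by frame with a weighted point-to-plane
least-mean-squares fit (nearest-point pairing → rigid fit → diagonal-scaling
refinement, iterated to convergence). The per-frame transform is initialized
and masked by a rough rigid transform fitted to sparsely annotated, linearly
interpolated landmarks. The manual baseline derives per-frame rigid transforms
from two landmarks (condylar superior for translation, gonion for rotation).
Derived kinematics (landmark pathways, inclination, instantaneous center of
rotation) and a statistical method comparison are included, along with a
synthetic phantom generator with ground-truth motion so the whole pipeline is
testable without patient data.

## Layout

| module | role |
| --- | --- |
| `jawtrack.geometry2d` | planar rigid/scaled transforms, SVD landmark fit, Pratt circle fit, ICR |
| `jawtrack.annotation` | areas, contours, named landmarks, keyframe rule, interpolation, rasterization |
| `jawtrack.extraction` | grey normalization, intensity lift, normal estimation, filtering, weighting |
| `jawtrack.registration` | pairing, superimposition error, point-to-plane LMS core, sequence tracking |
| `jawtrack.baseline_manual` | two-landmark manual tracking baseline |
| `jawtrack.pathways` | pathway propagation, inclination, ICR paths, distances, threshold tests |
| `jawtrack.synthetic` | phantom generator with ground-truth transforms and annotation |
| `jawtrack.io` / `jawtrack.cli` | TIFF/NIfTI/JSON/CSV I/O, configuration, command line |

Conventions: angles counterclockwise-positive in image coordinates
(x = column·spacing right, y = row·spacing down, origin at the center of the
top-left pixel); transforms act as `y = T + R·H·x`; frames are 1-based;
lengths in mm.

## CLI

```sh
# generate a phantom study (per-slice multi-page TIFFs + annotation JSON + ground truth)
jawtrack simulate --out study/ --frames 100 --slices 3 --noise-sigma 5 --seed 1

# automatic tracking
jawtrack track --images study/ --annotation study/annotation.json --out results/

# manual baseline from a landmark CSV (frame, cs_x, cs_y, go_x, go_y in mm)
jawtrack manual-track --landmarks study/true_landmarks.csv --out results/manual.csv

# run both methods and compare pathways / inclination
jawtrack compare --images study/ --annotation study/annotation.json \
    --landmarks study/true_landmarks.csv --out results/

# plot the error series
jawtrack report --transforms results/transforms.csv \
    --manual-errors results/manual_errors.csv --out results/errors.png
```

`--config` accepts a YAML/JSON mapping of `RegistrationConfig` fields
(`tol`, `max_iterations`, `vertical_filter_deg`, `condyle_weight`,
`middle_slice_weight`, `scale_bounds`, `icr_min_rotation_deg`, ...).

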
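import numpy as np
import pytest

from jawtrack.registration import RegistrationConfig, track_sequence
from jawtrack.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    """Quick phantom: 12 frames, 2 slices, reduced motion."""
    return PhantomSpec(n_frames=12, n_slices=2, max_translation_mm=6.0, max_rotation_deg=15.0)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def small_tracking(small_phantom):
    frames, truth = small_phantom
    return track_sequence(frames, truth.annotation, RegistrationConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def surface_cloud(nx=15, ny=15, spacing=1.0, fn=None, slice_id=1):
    """Handcrafted lifted cloud over a lattice with analytically varied normals."""
    from jawtrack.extraction import PointCloud, estimate_normals

    if fn is None:
        fn = lambda x, y: 0.05 * (x - nx / 2) ** 2 + 0.04 * (y - ny / 2) ** 2 + 0.3 * x
    cc, rr = np.meshgrid(np.arange(nx), np.arange(ny))
    rows, cols = rr.ravel(), cc.ravel()
    x, y = cols * spacing, rows * spacing
    z = fn(x, y)
    cloud = PointCloud(
        xyz=np.column_stack([x, y, z]),
        rows=rows.astype(np.intp),
        cols=cols.astype(np.intp),
        slice_ids=np.full(x.size, slice_id, dtype=np.intp),
        is_condyle=np.zeros(x.size, dtype=bool),
    )
    return estimate_normals(cloud)
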
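import numpy as np
import pytest

from qsmpipe import PhantomSpec, ROISpec, forward_field, make_phantom


@pytest.fixture(scope="session")
def sphere_phantom():
    """64-cube isotropic phantom with a single 100 ppb sphere (r = 8 vox)."""
    spec = PhantomSpec(
        grid_shape=(64, 64, 64),
        voxel_size_mm=(1.0, 1.0, 1.0),
        rois=(ROISpec("sphere", "sphere", (32, 32, 32), (8, 8, 8), 100.0),),
        brain_semiaxes_vox=(28, 28, 28),
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def sphere_field(sphere_phantom):
    return forward_field(sphere_phantom)


@pytest.fixture(scope="session")
def two_roi_phantom():
    """Anisotropic-grid phantom with +100/-50 ppb regions and a ventricle."""
    grid = (64, 64, 48)
    cx, cy, cz = 32, 32, 24
    spec = PhantomSpec(
        grid_shape=grid,
        rois=(
            ROISpec("csf", "ellipsoid", (cx, cy, cz), (3, 4, 5), 0.0, 200.0),
            ROISpec("pos", "ellipsoid", (cx - 9, cy - 5, cz - 4), (5, 5, 2), 100.0, 35.0),
            ROISpec("neg", "ellipsoid", (cx, cy + 10, cz), (5, 5, 2), -50.0, 55.0),
        ),
        n_coils=4,
        noise_sd=0.0,
        seed=7,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def two_roi_field(two_roi_phantom):
    return forward_field(two_roi_phantom)
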
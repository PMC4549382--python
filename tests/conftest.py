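import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import orseg as o
from orseg.prf import PRFGrid, default_lattice

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stim_cfg():
    # coarser raster than the default keeps the suite fast; aperture-grid
    # refinement invariance is tested separately
    return o.StimulusConfig(grid_n=81)


@pytest.fixture(scope="session")
def hrf():
    return o.HRFParams()


@pytest.fixture(scope="session")
def mapping_run(stim_cfg):
    return o.make_mapping_run(stim_cfg, 10, 14)


@pytest.fixture(scope="session")
def prf_grid(mapping_run, stim_cfg, hrf):
    ap, _ = mapping_run
    return PRFGrid(ap, hrf, default_lattice(stim_cfg.field_radius_deg))


@pytest.fixture(scope="session")
def retino_phantom():
    return o.make_retinotopic_phantom()


@pytest.fixture(scope="session")
def or_phantom():
    return o.make_or_phantom()


@pytest.fixture(scope="session")
def or_run(or_phantom):
    params = o.TrackingParams(n_streamlines=10_000, max_length_mm=150.0)
    return o.run_or_pipeline(or_phantom, params, seed=1)


@pytest.fixture(scope="session")
def labeled_tractogram():
    return o.make_labeled_tractogram()


@pytest.fixture(scope="session")
def uniform_y_field():
    """Uniform tensor field with principal axis +y, 1 mm voxels."""
    shape = (20, 40, 20)
    D = np.zeros((*shape, 3, 3))
    D[...] = np.diag([0.2e-3, 1.7e-3, 0.2e-3])
    field = o.TensorField(np.ascontiguousarray(D), np.eye(4))
    return field
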
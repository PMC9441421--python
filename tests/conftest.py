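import numpy as np
import pytest

import dwialps as d


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default noiseless phantom study with its ground-truth record."""
    spec = d.default_phantom_spec()
    study, truth = d.generate_phantom(spec, seed=0)
    return spec, study, truth


@pytest.fixture(scope="session")
def noiseless_maps(noiseless_phantom):
    _, study, _ = noiseless_phantom
    return d.compute_adc(study)


@pytest.fixture(scope="session")
def default_rois():
    return d.default_roi_set()


@pytest.fixture
def tiny_study():
    """Small well-formed study: isotropic decay with D = 1.0e-3 mm^2/s."""
    shape = (8, 8, 4)
    s0 = np.full(shape, 1000.0)
    si = s0 * np.exp(-1.0)
    return d.DiffusionStudy(
        s0=s0, s_x=si.copy(), s_y=si.copy(), s_z=si.copy(), b_value=1000.0,
        subject_id="tiny",
    )
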
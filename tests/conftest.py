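import numpy as np
import pytest

from svoct.angiography import speckle_variance_volume
from svoct.synthetic import (
    CylinderFieldSpec,
    SpeckleSimSpec,
    generate_parallel_cylinders,
    simulate_bscan_stack,
)


@pytest.fixture(scope="session")
def cylinder_phantom():
    """Moderate-density parallel-cylinder phantom on an anisotropic
    acquisition-like grid, with ground truth."""
    spec = CylinderFieldSpec(
        box_size=(400.0, 1000.0, 500.0),
        r_c=20.0,
        line_density=1.5e-5,
        axis="y",
        seed=11,
    )
    return generate_parallel_cylinders(spec, voxel_spacing=(4.0, 5.0, 5.0))


@pytest.fixture(scope="session")
def simulated_stack(cylinder_phantom):
    return simulate_bscan_stack(cylinder_phantom.mask, SpeckleSimSpec(seed=11))


@pytest.fixture(scope="session")
def sv_volume(simulated_stack):
    return speckle_variance_volume(simulated_stack)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
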
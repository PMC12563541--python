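import numpy as np
import pytest

from aosim import OpticalConfig, VirtualScope, ZernikeVector, make_bead_phantom


@pytest.fixture(scope="session")
def config():
    return OpticalConfig()


@pytest.fixture(scope="session")
def bead_scene(config):
    """Sparse planar bead field used by the correction tests."""
    return make_bead_phantom(8, diameter_nm=100.0, fov=(1, 128, 128),
                             min_separation_nm=1800.0, seed=11,
                             config=config)


@pytest.fixture()
def noiseless_scope(bead_scene, config):
    def factory(sample_aberration=None, **kw):
        return VirtualScope(bead_scene, config,
                            sample_aberration=sample_aberration, **kw)
    return factory
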
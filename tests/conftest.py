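import numpy as np
import pytest

from hergchar.model import BEATTIE_REFERENCE, IonicEnvironment
from hergchar.protocol import build_staircase
from hergchar.synthetic import PlateConfig, generate_dataset


@pytest.fixture(scope="session")
def env():
    return IonicEnvironment()


@pytest.fixture(scope="session")
def ref_params():
    return BEATTIE_REFERENCE


@pytest.fixture(scope="session")
def staircase():
    """Staircase protocol on the desk-scale 2 kHz grid."""
    return build_staircase().with_sampling_interval(5e-4)


@pytest.fixture(scope="session")
def staircase_1khz():
    """Coarser grid used for the inference studies."""
    return build_staircase().with_sampling_interval(1e-3)


@pytest.fixture(scope="session")
def plate(env):
    """A 16-well synthetic plate with one designed failure per mode."""
    return generate_dataset(PlateConfig(n_wells=16, fail_fraction=0.25), seed=7, env=env)
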
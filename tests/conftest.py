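import numpy as np
import pytest

from diffct import (DetectorGeometry, ProjectorConfig, VolumeGeometry,
                    cone_beam, fan_beam, parallel_beam)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_parallel():
    """16x16 volume, 23-pixel detector, 24 views over pi."""
    vol = VolumeGeometry((16, 16), (1.0, 1.0))
    det = DetectorGeometry((23,), (1.0,))
    return parallel_beam(vol, det, 24, np.pi)


@pytest.fixture(scope="session")
def tiny_fan():
    vol = VolumeGeometry((16, 16), (1.0, 1.0))
    det = DetectorGeometry((23,), (1.0,))
    return fan_beam(vol, det, 24, sid=50.0, sdd=80.0)


@pytest.fixture(scope="session")
def tiny_cone():
    vol = VolumeGeometry((8, 8, 8), (1.0, 1.0, 1.0))
    det = DetectorGeometry((10, 10), (1.0, 1.0))
    return cone_beam(vol, det, 12, sid=50.0, sdd=80.0)


@pytest.fixture(scope="session")
def default_cfg():
    return ProjectorConfig()
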
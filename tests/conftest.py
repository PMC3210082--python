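import numpy as np
import pytest

import venoquant as vq


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_tube_truth():
    """Small through-plane two-tube phantom on the acquisition-like grid."""
    sp = (0.33, 0.33, 2.0)
    dims = (64, 64, 12)
    lz = 11 * 2.0
    tubes = [
        vq.TubeSpec(start_mm=(6.0, 8.0, 0.0), end_mm=(7.5, 9.0, lz), radius_mm=0.5),
        vq.TubeSpec(start_mm=(14.0, 14.0, 0.0), end_mm=(15.0, 12.5, lz), radius_mm=0.9),
    ]
    return vq.make_tube_volume(tubes, dims, sp, background=100.0, noise_sd=2.0, seed=7)
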
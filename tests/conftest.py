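import logging

import numpy as np
import pytest

from wingsignal.spectra import illuminant_d65like, make_camera, make_visual_system

logging.getLogger("wingsignal").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def camera():
    return make_camera()


@pytest.fixture(scope="session")
def illum():
    return illuminant_d65like()


@pytest.fixture(scope="session")
def uvs():
    return make_visual_system("UVS")


@pytest.fixture(scope="session")
def vs():
    return make_visual_system("VS")


def rnl_distance_oracle(catch_a, catch_b, noise):
    """Independent receptor-noise-limited distance: log-catch differences
    projected orthogonally to the achromatic direction under the inverse
    noise metric. Written against the general n-receptor model, independent
    of the pairwise/triple expansion used by the implementation."""
    df = np.log(np.asarray(catch_a, float) / np.asarray(catch_b, float))
    v_inv = np.diag(1.0 / np.asarray(noise, float) ** 2)
    one = np.ones(len(df))
    m = v_inv - v_inv @ np.outer(one, one) @ v_inv / (one @ v_inv @ one)
    return float(np.sqrt(df @ m @ df))
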
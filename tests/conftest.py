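"""Shared fixtures: small images, windows, and a session-scoped texture pair."""

import numpy as np
import pytest

from peritex import (
    GrayImage,
    PoolingWindow,
    PSParams,
    ProceduralTextureParams,
    make_texture_pair,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def noise_image():
    r = np.random.default_rng(7)
    return GrayImage(r.random((128, 128)), px_per_deg=7.5)


@pytest.fixture(scope="session")
def small_params():
    return PSParams(pooling_diameter_px=90)


@pytest.fixture(scope="session")
def small_window():
    return PoolingWindow.disk((128, 128), 90)


@pytest.fixture(scope="session")
def texture_pair():
    """Structured texture + phase-scrambled counterpart (512 px source)."""
    return make_texture_pair(ProceduralTextureParams(size_px=512, rng_seed=11))
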
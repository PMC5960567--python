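"""Shared fixtures: small synthetic scenes built once per session."""

import numpy as np
import pytest

from noarsa import phantom, registration


@pytest.fixture(scope="session")
def scene05():
    """Phantom scene at 0.5 mm pixel spacing (600 px detector)."""
    return phantom.make_scene(seed=1, pixel_spacing=0.5)


@pytest.fixture(scope="session")
def binary_pair05(scene05):
    """Noise-free binary stereo radiographs of scene05."""
    return [phantom.simulate_radiograph(scene05, v, mode="binary") for v in range(2)]


@pytest.fixture(scope="session")
def problem05(scene05, binary_pair05):
    """NOA problem for scene05 with the margin sized for ±5 mm/deg offsets."""
    views = [
        registration.View(dr, cam)
        for dr, cam in zip(binary_pair05, scene05.cameras)
    ]
    margin = phantom.margin_for(scene05, 5.0)
    return registration.NOAProblem(scene05.mesh, views, margin_px=margin)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
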
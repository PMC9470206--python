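"""Shared fixtures: small arenas, grid-valued random sequences, rendered fish."""

import numpy as np
import pytest

from bmassay import ArenaGeometry, PeriodDesign, PointLightSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def arena():
    """Default assay geometry with a coarse pixel scale (fast rendering)."""
    return ArenaGeometry(px_per_cm=10.0)


@pytest.fixture
def design():
    return PeriodDesign()


def grid_sequence(rng, n_frames=20, n_dots=6, fps=60.0):
    """Random sequence with dyadic-grid coordinates (multiples of 1/64).

    Pixel-quantised like real tracking data; reflection and finite-difference
    arithmetic on these values is exact in double precision.
    """
    coords = rng.integers(0, 2**12, size=(n_frames, n_dots, 2)).astype(float) / 64.0
    return PointLightSequence(coords, fps=fps)


@pytest.fixture
def grid_seq(rng):
    return grid_sequence(rng)
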
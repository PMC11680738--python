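"""Shared fixtures: small 2D/3D simulation setups reused across tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import ztefill as z
from ztefill.nufft import NufftPlan


@pytest.fixture(scope="session")
def traj2d_small():
    """102 paired spokes, 64-sample readout at 2x oversampling (64^2 scale)."""
    return z.make_uniform_spokes_2d(102, 64, 2.0)


@pytest.fixture(scope="session")
def disc64():
    return z.make_disc_phantom(64, outer_radius=20, inner_radius=10)


@pytest.fixture(scope="session")
def smooth_disc64():
    img = gaussian_filter(
        z.make_disc_phantom(64, outer_radius=20, inner_radius=10).values.real,
        1.5,
    )
    return z.ImageVolume(img)


@pytest.fixture(scope="session")
def maps2d_small(disc64):
    return z.make_coil_maps(disc64.shape, n_coils=4, seed=11)


@pytest.fixture(scope="session")
def plan2d_small(traj2d_small, disc64):
    return NufftPlan(
        traj2d_small.coords.reshape(-1, 2), disc64.shape
    )


@pytest.fixture(scope="session")
def kspace2d_small(smooth_disc64, maps2d_small, traj2d_small, plan2d_small):
    """Noiseless multi-coil k-space of the smooth disc (fully acquired)."""
    return z.simulate_kspace(
        smooth_disc64, maps2d_small, traj2d_small, plan=plan2d_small
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
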
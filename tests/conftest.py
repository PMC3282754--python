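"""Shared fixtures: analytic rate-map builders and cached synthetic sessions."""

from __future__ import annotations

import numpy as np
import pytest

from placeburst.maps import RateMap, domain_mask, grid_size
from placeburst.synthetic import SyntheticCellParams, TrajectoryParams, simulate_place_cell, simulate_trajectory


def make_map(rate_fn, arena_radius=15.0, pixel_size=1.0, occupancy=1.0):
    """RateMap with analytically assigned rates (uniform occupancy).

    ``rate_fn(cx, cy)`` receives pixel-center coordinate grids.
    """
    n = grid_size(arena_radius, pixel_size)
    dom = domain_mask(arena_radius, pixel_size)
    rm = RateMap(
        rate=np.zeros((n, n)),
        occupancy=np.where(dom, occupancy, 0.0),
        valid=dom.copy(),
        pixel_size=pixel_size,
        arena_radius=arena_radius,
    )
    c = rm.x0 + (np.arange(n) + 0.5) * pixel_size
    cx = np.broadcast_to(c[:, None], (n, n))
    cy = np.broadcast_to(c[None, :], (n, n))
    rm.rate = np.where(dom, np.asarray(rate_fn(cx, cy), dtype=float), 0.0)
    return rm


def gaussian_map(center=(7.0, 0.0), width=4.0, peak=5.0, noise_sd=0.0, seed=0, **kwargs):
    """Smooth Gaussian place-field map, optionally with iid pixel noise."""
    rng = np.random.default_rng(seed)

    def f(cx, cy):
        r = peak * np.exp(-((cx - center[0]) ** 2 + (cy - center[1]) ** 2) / (2 * width**2))
        if noise_sd > 0:
            r = r + noise_sd * rng.standard_normal(cx.shape)
        return r

    return make_map(f, **kwargs)


@pytest.fixture(scope="session")
def short_track():
    """A 300-s foraging trajectory (cached for the whole test run)."""
    return simulate_trajectory(TrajectoryParams(duration=300.0, seed=11))


@pytest.fixture(scope="session")
def place_cell_session(short_track):
    """A bursty place cell recorded along ``short_track``."""
    params = SyntheticCellParams(
        field_center=(6.0, 2.0), peak_event_rate=6.0, p_single=0.5, intra_isi_mean=3.0
    )
    spikes = simulate_place_cell(short_track, params, seed=21)
    return spikes, short_track, params
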
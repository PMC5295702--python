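"""Shared fixtures.

The heavy field simulations are session-scoped so that unit tests and the
acceptance suite reuse one integration pass each.  Everything is
deterministic: fixed seeds, fixed-step integration.
"""

from __future__ import annotations

import numpy as np
import pytest

from wcfield.core_model import TYPE_I_PARAMS, TYPE_II_PARAMS
from wcfield.spatial_field import FieldParams, StimulusSpec, simulate_field_batch
from wcfield.wave_analysis import one_to_one_threshold, propagation_regime_sweep

#: coarse grid used throughout the test suite (dx = 0.02 mm keeps runs fast
#: while staying well inside the dx <= sigma_i/5 sampling guard)
COARSE_DX = 0.02


@pytest.fixture(scope="session")
def type_ii():
    return TYPE_II_PARAMS


@pytest.fixture(scope="session")
def type_i():
    return TYPE_I_PARAMS


@pytest.fixture(scope="session")
def field_coarse():
    return FieldParams(dx=COARSE_DX)


@pytest.fixture(scope="session")
def field_coarse_type_i():
    return FieldParams(dx=COARSE_DX, b_i=8.0)


@pytest.fixture(scope="session")
def regime_sweep(field_coarse):
    """Propagation survey over tau_i/tau_e at the Fig-3 stimulation level."""
    ratios = [2.0, 3.0, 3.9, 4.5, 6.0, 8.0, 10.0, 11.5, 12.5, 14.0, 16.0]
    return propagation_regime_sweep(
        field_coarse, StimulusSpec(J_e=1.3), ratios, duration=300.0, settle=0.0
    )


@pytest.fixture(scope="session")
def mode_locking_trajs(field_coarse_type_i):
    """Focally converted type I medium at the three stimulation levels."""
    jes = np.array([1.5, 2.2, 3.0])
    trajs = simulate_field_batch(
        field_coarse_type_i, StimulusSpec(J_i=4.0), 450.0,
        dt=0.05, store_every=10, stim_J_e=jes, stim_J_i=4.0,
    )
    return dict(zip(jes.tolist(), trajs))


@pytest.fixture(scope="session")
def one_to_one_scan(field_coarse_type_i):
    """Ratio x current scan for 1:1 wave emission in the converted medium."""
    return one_to_one_threshold(field_coarse_type_i)


@pytest.fixture(scope="session")
def rescaled_traj():
    """Spatially rescaled beat-skipping medium (space constants x3)."""
    params = FieldParams(dx=COARSE_DX, b_i=8.0, sigma_e=0.6, sigma_i=0.3,
                         tau_e=1.8, tau_i=3.6)
    return simulate_field_batch(
        params, StimulusSpec(J_e=3.0, J_i=4.0, width=1.2), 400.0,
        dt=0.05, store_every=10,
    )[0]
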
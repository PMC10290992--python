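"""Shared fixtures: phantom study conditions and small random series.

Scenario-scale conditions (N=32, T=20, ~8% k-space sampled per frame, noise
sigma 0.01) are fixed here once and reused by the unit and acceptance suites.
"""

from __future__ import annotations

import numpy as np
import pytest

import cinekalman as ck

# study conditions for the scenario suite
GRID_N = 32
PHASES_T = 20
N_CYCLES = 3
TRUNCATE_AT = 12
SKIP_STRIDE = 2
TEMPORAL_FACTOR = 5
N_SPOKES = 3  # ~12% of grid points; acceleration pi*N/(2*3) ~ 16.8
N_PE = 3  # ~9% of grid points
NOISE_SIGMA = 0.01
R_SIGMA2 = NOISE_SIGMA**2
P0_SIGMA2 = 1e-3


@pytest.fixture(scope="session")
def phantom_pair():
    """Training cycle and distinct test heartbeat at scenario scale."""
    return ck.phantom.make_phantom_pair(GRID_N, PHASES_T, seed=0)


@pytest.fixture(scope="session")
def small_pair():
    """Cheap phantom pair for operator-level tests."""
    return ck.phantom.make_phantom_pair(16, 8, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_series(rng, T=6, N=4, complex_valued=True):
    """Generic random cine (centered rank T-1) for oracle tests."""
    frames = rng.standard_normal((T, N, N))
    if complex_valued:
        frames = frames + 1j * rng.standard_normal((T, N, N))
    return ck.CineSeries(
        frames=frames, phase_labels=np.arange(1, T + 1), period_T=T, is_training=True
    )


def scenario_kframes(train, test, kind, sampling, seed, n_cycles=N_CYCLES):
    """Build ground truth, schedule, and measured k-space for one scenario."""
    spec = ck.ScenarioSpec(
        kind=kind,
        n_cycles=n_cycles,
        truncate_at_phase=TRUNCATE_AT,
        skip_stride=SKIP_STRIDE,
        upsample_factor=TEMPORAL_FACTOR,
    )
    truth, sched = ck.build_scenario(train, test, spec)
    truth = ck.rescale_means(truth, train)
    N = train.grid_size
    if sampling == "radial":
        pats = [ck.radial_trajectory(N, N_SPOKES, frame_index=i) for i in range(truth.n_frames)]
    elif sampling == "cartesian":
        pats = ck.cartesian_mask(N, N_PE, seed=0)
    else:
        pats = ck.spiral_trajectory(N)
    kframes = ck.measure_series(truth, pats, noise_sigma=NOISE_SIGMA, seed=seed)
    return truth, sched, kframes
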
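"""Shared fixtures: desk-scale simulation runs reused across tests.

The simulations here are deliberately small (128^2 grid on a 20.48 box)
so the whole suite stays within a laptop-scale budget; the scientific
content (state sequence, effective radius, spin/mode observables) is
unchanged from the larger default configuration.
"""

from __future__ import annotations

import numpy as np
import pytest

from vortexwell.fields import WellGeometry
from vortexwell.ttshe import (
    SimulationConfig, Simulation, eigenmode_initial_condition, integrate,
)

GRID_N = 128
DOMAIN = 20.48
CENTER = (DOMAIN / 2, DOMAIN / 2)


def run_single_well(
    R: float, t_end: float, *, grid_n: int = GRID_N, seed: int = 0,
    save_every: float = 1.0, seed_vortex: bool = True, perturb: float = 1e-2,
    t_start_save: float = 0.0,
):
    """Integrate a single-well configuration, returning the saved frames.

    Runs start from the axisymmetric eigenmode plus a small random
    perturbation: this reaches the attractor of the confined dynamics in
    a fraction of the time a pure-noise start needs, while the
    perturbation lets non-axisymmetric instabilities (reversal,
    four-vortex pulsation, turbulence) develop.
    """
    well = WellGeometry(CENTER, R)
    cfg = SimulationConfig(grid_n=grid_n, domain_size=DOMAIN, wells=(well,),
                           t_end=t_end, save_every=save_every, seed=seed)
    rng = np.random.default_rng(seed)
    if seed_vortex:
        w0 = eigenmode_initial_condition(cfg, well)
        w0 = w0 + perturb * rng.standard_normal(w0.shape)
    else:
        w0 = None
    sim = Simulation(cfg, w0)
    frames = []
    n_steps = int(round(t_end / cfg.dt))
    every = max(1, int(round(save_every / cfg.dt)))
    for i in range(n_steps):
        sim.step()
        if (i + 1) % every == 0 and sim.t >= t_start_save:
            frames.append(sim.snapshot())
    return frames, well


@pytest.fixture(scope="session")
def stable_vortex_run():
    """R = 5.2: single stabilized vortex."""
    return run_single_well(5.2, 300.0, t_start_save=100.0)


@pytest.fixture(scope="session")
def reversing_run():
    """R = 5.6: periodically reversing two-vortex state."""
    return run_single_well(5.6, 700.0, t_start_save=150.0)


@pytest.fixture(scope="session")
def four_vortex_run():
    """R = 6.4: pulsating four-vortex state."""
    return run_single_well(6.4, 400.0, t_start_save=150.0)


@pytest.fixture(scope="session")
def turbulent_run():
    """R = 7.6: irregular (turbulent) state."""
    return run_single_well(7.6, 300.0, t_start_save=100.0)


@pytest.fixture(scope="session")
def unconfined_turbulence_frames():
    """No wells: saturated active turbulence, finely sampled for regression."""
    cfg = SimulationConfig(grid_n=GRID_N, domain_size=DOMAIN, wells=(),
                           t_end=40.0, save_every=1.0, seed=3)
    sim = Simulation(cfg)
    for _ in range(int(40.0 / cfg.dt)):
        sim.step()
    frames = [sim.snapshot()]
    # 30 frames at 0.05 spacing for centered time differences
    for _ in range(30):
        for _ in range(5):
            sim.step()
        frames.append(sim.snapshot())
    return frames
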
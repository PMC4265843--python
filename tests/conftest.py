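"""Shared fixtures: a session-scoped RD null and composite-track builders."""
from __future__ import annotations

import numpy as np
import pytest

from hoptrack import SimulationConfig, Trajectory, build_rd_null, simulate_trajectory


@pytest.fixture(scope="session")
def null_160_40():
    """RD null at the fast-fluorescence scale (N=160, n=40, δt=0.5 ms)."""
    return build_rd_null(N=160, n=40, delta_t=5e-4, n_sims=2000, seed=101)


@pytest.fixture(scope="session")
def trap_track_factory():
    """Build trap-and-escape tracks: confined in an L-box, then free.

    The trapped interval occupies frames [0, trap_frames); localization noise
    is added to the composite path.
    """

    def make(track_id: str, *, trap_frames: int, total: int, L: float,
             D: float, delta_t: float, loc_sigma: float, seed: int) -> Trajectory:
        conf = simulate_trajectory(
            SimulationConfig(mode="confined", D_micro=D, compartment=(L, L),
                             delta_t=delta_t, n_frames=trap_frames, substeps=80,
                             loc_sigma=0.0),
            seed, track_id,
        )
        free = simulate_trajectory(
            SimulationConfig(mode="free", D_micro=D, delta_t=delta_t,
                             n_frames=total - trap_frames + 1, substeps=1,
                             loc_sigma=0.0),
            seed + 1, track_id,
        )
        x = np.concatenate([conf.x, conf.x[-1] + free.x[1:] - free.x[0]])
        y = np.concatenate([conf.y, conf.y[-1] + free.y[1:] - free.y[0]])
        rng = np.random.default_rng(seed + 2)
        x = x + rng.normal(0.0, loc_sigma, x.size)
        y = y + rng.normal(0.0, loc_sigma, y.size)
        return Trajectory(track_id, delta_t, np.arange(total) * delta_t, x, y)

    return make
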
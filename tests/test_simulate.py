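"""Generator correctness: invariants of the four motion models."""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from hoptrack import (
    ConfigurationError,
    SimulationConfig,
    calibrate_p_hop,
    compute_msd,
    ensemble_msd,
    estimate_D24,
    estimate_dmacro,
    estimate_noise_floor,
    simulate_ensemble,
    simulate_trajectory,
)


@pytest.mark.parametrize(
    "kwargs, match",
    [
        ({"mode": "ballistic"}, "unknown mode"),
        ({"mode": "free", "D_micro": -1.0}, "D_micro"),
        ({"mode": "hop", "p_hop": 1.5}, "p_hop"),
        ({"mode": "free", "substeps": 0}, "substeps"),
        ({"mode": "free", "loc_sigma": -0.01}, "loc_sigma"),
        ({"mode": "confined", "compartment": (0.0, 0.1)}, "compartment"),
    ],
)
def test_invalid_configs_raise(kwargs, match):
    with pytest.raises(ConfigurationError, match=match):
        SimulationConfig(**kwargs).validate()


def test_substep_invariant_error_names_the_ratio():
    # RMS substep = sqrt(2*5*5e-4) ≈ 0.071 µm >> 85 nm / 10
    cfg = SimulationConfig(mode="hop", D_micro=5.0, compartment=(0.085, 0.085),
                           delta_t=5e-4, substeps=1)
    with pytest.raises(ConfigurationError, match="ratio"):
        cfg.validate()


def test_ensembles_are_deterministic_and_tracks_independent():
    cfg = SimulationConfig(mode="hop", D_micro=2.0, compartment=(0.1, 0.1),
                           p_hop=0.1, delta_t=1e-4, n_frames=50, substeps=4,
                           loc_sigma=0.01, n_traj=3, seed=42)
    a = simulate_ensemble(cfg)
    b = simulate_ensemble(cfg)
    for ta, tb in zip(a, b):
        np.testing.assert_array_equal(ta.x, tb.x)
        np.testing.assert_array_equal(ta.y, tb.y)
    assert not np.array_equal(a[0].x, a[1].x)


def test_zero_diffusion_zero_noise_is_stationary():
    cfg = SimulationConfig(mode="free", D_micro=0.0, delta_t=1e-3,
                           n_frames=20, substeps=2, loc_sigma=0.0)
    tr = simulate_trajectory(cfg, seed=1)
    assert np.all(tr.x == tr.x[0]) and np.all(tr.y == tr.y[0])


def test_pure_drift_msd_is_exactly_ballistic():
    cfg = SimulationConfig(mode="directed", D_micro=0.0, drift=(1.0, 0.0),
                           delta_t=1e-3, n_frames=30, substeps=1, loc_sigma=0.0)
    curve = compute_msd(simulate_trajectory(cfg, seed=0), max_lag=10)
    expected = (np.arange(1, 11) * 1e-3) ** 2  # (n · v · δt)², v = 1 µm/s
    np.testing.assert_allclose(curve.msd_raw, expected, rtol=1e-10)


def test_confined_positions_never_leave_the_box():
    lx, ly = 0.08, 0.12
    cfg = SimulationConfig(mode="confined", D_micro=3.0, compartment=(lx, ly),
                           delta_t=2e-5, n_frames=2000, substeps=4, loc_sigma=0.0)
    for seed in range(5):
        tr = simulate_trajectory(cfg, seed=seed)
        assert np.all((tr.x >= 0) & (tr.x <= lx))
        assert np.all((tr.y >= 0) & (tr.y <= ly))


@pytest.mark.parametrize("mode", ["confined", "hop"])
def test_long_run_msd_saturates_at_box_variance(mode):
    # Stationary uniform positions in a box: displacement variance L²/6 per axis.
    lx, ly = 0.08, 0.1
    cfg = SimulationConfig(mode=mode, D_micro=3.0, compartment=(lx, ly),
                           p_hop=0.0, delta_t=2e-5, n_frames=1500, substeps=4,
                           loc_sigma=0.0, n_traj=40, seed=7)
    curves = [compute_msd(tr, max_lag=400) for tr in simulate_ensemble(cfg)]
    ens = ensemble_msd(curves)
    plateau = lx**2 / 6 + ly**2 / 6
    tail = ens.mean[200:]
    assert np.abs(tail.mean() - plateau) / plateau < 0.05


def test_free_ensemble_msd_matches_4dt_plus_noise_offset():
    d_true, sigma = 1.0, 0.02
    cfg = SimulationConfig(mode="free", D_micro=d_true, delta_t=5e-4, n_frames=64,
                           substeps=1, loc_sigma=sigma, n_traj=1000, seed=5)
    curves = [compute_msd(tr, max_lag=10) for tr in simulate_ensemble(cfg)]
    # raw ensemble mean (no noise subtraction) vs 4DΔt + 4σ²
    ens = ensemble_msd(curves)
    theory = 4 * d_true * ens.lag_time + 4 * sigma**2
    assert np.all(np.abs(ens.mean - theory) < 3 * ens.se)
    assert abs(ens.slope / 4 - d_true) < 0.05


def test_fully_permeable_barriers_reproduce_free_d24():
    # p_hop = 1 is free diffusion: ensemble D_2-4 within 3 SE of D_micro.
    d_true = 6.4
    cfg = SimulationConfig(mode="hop", D_micro=d_true, compartment=(1.0, 1.0),
                           p_hop=1.0, delta_t=5e-4, n_frames=160, substeps=64,
                           loc_sigma=0.0, n_traj=300, seed=9)
    d24 = np.array(
        [estimate_D24(estimate_noise_floor(compute_msd(tr, max_lag=4)))
         for tr in simulate_ensemble(cfg)]
    )
    se = d24.std(ddof=1) / np.sqrt(d24.size)
    assert abs(d24.mean() - d_true) < 3 * se


def test_emergent_dmacro_monotone_in_hop_probability():
    dmac = []
    for p in (0.01, 0.1, 1.0):
        cfg = SimulationConfig(mode="hop", D_micro=5.0, compartment=(0.085, 0.085),
                               p_hop=p, delta_t=2e-5, n_frames=500, substeps=4,
                               loc_sigma=0.0, n_traj=64, seed=13)
        dmac.append(estimate_dmacro(simulate_ensemble(cfg)))
    assert dmac[0] < dmac[1] < dmac[2]
    assert abs(dmac[2] - 5.0) / 5.0 < 0.2  # p=1 recovers free diffusion


def test_substep_refinement_converges_at_fixed_permeability():
    # p_hop is a per-attempt probability, so halving the substep length
    # multiplies the barrier-encounter rate by sqrt(2); rescaling
    # p_hop -> p_hop / sqrt(2) keeps the physical permeability fixed, and the
    # ensemble MSD must then agree within Monte Carlo error.
    base = dict(mode="hop", D_micro=5.0, compartment=(0.085, 0.085),
                delta_t=2e-5, n_frames=400, loc_sigma=0.0, n_traj=192, seed=17)
    ens = {}
    for s, p in ((4, 0.05), (8, 0.05 / np.sqrt(2))):
        cfg = SimulationConfig(**base, substeps=s, p_hop=p)
        ens[s] = ensemble_msd(
            [compute_msd(tr, max_lag=60) for tr in simulate_ensemble(cfg)]
        )
    diff = np.abs(ens[4].mean - ens[8].mean)
    combined_se = np.sqrt(ens[4].se**2 + ens[8].se**2)
    assert np.mean(diff <= 3 * combined_se) > 0.9


def test_confined_sampling_is_substep_independent():
    # reflecting walls are applied by exact path folding, so the sampled
    # frame positions are distributed identically for any substep count
    base = dict(mode="confined", D_micro=3.0, compartment=(0.1, 0.1),
                delta_t=2e-5, n_frames=300, loc_sigma=0.0, n_traj=150, seed=19)
    ens = {}
    for s in (2, 16):
        cfg = SimulationConfig(**base, substeps=s)
        ens[s] = ensemble_msd(
            [compute_msd(tr, max_lag=40) for tr in simulate_ensemble(cfg)]
        )
    diff = np.abs(ens[2].mean - ens[16].mean)
    combined_se = np.sqrt(ens[2].se**2 + ens[16].se**2)
    assert np.mean(diff <= 3 * combined_se) > 0.9


def test_calibrate_p_hop_hits_target_dmacro():
    cfg = SimulationConfig(mode="hop", D_micro=5.0, compartment=(0.085, 0.085),
                           delta_t=2e-5, substeps=4, loc_sigma=0.0, seed=23)
    target = 1.0
    p, achieved = calibrate_p_hop(cfg, target, n_traj=64, n_frames=600)
    assert 0.0 < p < 1.0
    assert abs(achieved - target) / target < 0.1
    # targeting D_micro itself returns fully permeable barriers
    p_free, _ = calibrate_p_hop(cfg, 5.0, n_traj=32, n_frames=300)
    assert p_free == 1.0
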
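"""RD statistic, Monte Carlo null calibration and mode classification."""
from __future__ import annotations

import numpy as np
import pytest

from hoptrack import (
    MSDCurve,
    SimulationConfig,
    Trajectory,
    TrackTooShortError,
    UndefinedRDError,
    build_rd_null,
    classify_mobility,
    classify_tracks,
    classify_trajectory,
    compute_msd,
    estimate_noise_floor,
    fraction_simple,
    rd_statistic,
    simulate_ensemble,
    simulate_trajectory,
)
from hoptrack.classify import ModeResult


def _linear_curve(D=2.0, delta_t=5e-4, n_lags=40):
    lag_t = np.arange(1, n_lags + 1) * delta_t
    return MSDCurve(lag_time=lag_t, msd_raw=4 * D * lag_t,
                    n_pairs=np.arange(160 - 1, 160 - 1 - n_lags, -1),
                    N=160, delta_t_frame=delta_t)


def test_rd_is_one_for_exactly_linear_msd():
    curve = _linear_curve()
    for n in (5, 20, 40):
        assert rd_statistic(curve, n) == pytest.approx(1.0)


def test_rd_of_ballistic_track_approaches_n_over_6():
    v, dt, n = 3.0, 5e-4, 40
    tr = Trajectory("b", dt, np.arange(160) * dt,
                    v * np.arange(160) * dt, np.zeros(160))
    curve = estimate_noise_floor(compute_msd(tr, max_lag=n))
    rd = rd_statistic(curve, n)
    # exact finite-n value (n² + 25/3)/(6n); ≈ n/6 = 6.67 at n = 40
    assert rd == pytest.approx((n**2 + 25 / 3) / (6 * n), rel=1e-6)
    assert rd == pytest.approx(n / 6, rel=0.01)


def test_rd_undefined_when_d24_nonpositive():
    lag_t = np.arange(1, 11) * 1e-3
    curve = MSDCurve(lag_time=lag_t, msd_raw=np.full(10, 1e-3) - 1e-5 * lag_t / lag_t[0],
                     n_pairs=np.arange(10, 0, -1), N=11, delta_t_frame=1e-3)
    with pytest.raises(UndefinedRDError):
        rd_statistic(estimate_noise_floor(curve), 8)


def test_null_distribution_properties(null_160_40):
    null = null_160_40
    assert null.rd_min < 1.0 < null.rd_max
    assert np.abs(null.rd_values.mean() - 1.0) < 0.02
    with pytest.raises(ValueError, match="n_sims"):
        build_rd_null(160, 40, 5e-4, n_sims=500)


def test_null_thresholds_scale_free_in_d(null_160_40):
    # RD is scale-free: a null simulated at a different D (same seed) is identical.
    other = build_rd_null(160, 40, 5e-4, n_sims=2000, seed=101, D=5.0)
    assert other.rd_min == pytest.approx(null_160_40.rd_min, rel=1e-9)
    assert other.rd_max == pytest.approx(null_160_40.rd_max, rel=1e-9)
    # and at a fresh seed it moves by at most ~2%
    fresh = build_rd_null(160, 40, 5e-4, n_sims=2000, seed=202, D=3.0)
    assert fresh.rd_min == pytest.approx(null_160_40.rd_min, rel=0.05)
    assert fresh.rd_max == pytest.approx(null_160_40.rd_max, rel=0.05)


def test_fresh_brownian_set_tail_fractions(null_160_40):
    cfg = SimulationConfig(mode="free", D_micro=1.0, delta_t=5e-4, n_frames=160,
                           substeps=1, loc_sigma=0.0, n_traj=2000, seed=303)
    results, _ = classify_tracks(simulate_ensemble(cfg), null_160_40)
    modes = np.array([r.mode for r in results])
    n = len(modes)
    se = np.sqrt(0.025 * 0.975 / n)
    assert abs(np.mean(modes == "suppressed") - 0.025) < 3 * se
    assert abs(np.mean(modes == "directed") - 0.025) < 3 * se
    assert abs(fraction_simple(results) - 0.95) < 3 * np.sqrt(0.95 * 0.05 / n)


def test_rd_invariant_under_rescaling_and_axis_swap():
    tr = simulate_trajectory(
        SimulationConfig(mode="free", D_micro=2.0, delta_t=5e-4, n_frames=160,
                         substeps=1, loc_sigma=0.0), seed=5)
    rd0 = rd_statistic(estimate_noise_floor(compute_msd(tr, max_lag=40)), 40)
    scaled = Trajectory("s", tr.delta_t, tr.t, 3.7 * tr.x, 3.7 * tr.y)
    swapped = Trajectory("w", tr.delta_t, tr.t, tr.y, tr.x)
    for other in (scaled, swapped):
        rd = rd_statistic(estimate_noise_floor(compute_msd(other, max_lag=40)), 40)
        assert rd == pytest.approx(rd0, rel=1e-9)


def test_mobility_filter(null_160_40):
    rng = np.random.default_rng(8)
    still = Trajectory("still", 5e-4, np.arange(160) * 5e-4,
                       rng.normal(0, 0.02, 160), rng.normal(0, 0.02, 160))
    curve = estimate_noise_floor(compute_msd(still, max_lag=40))
    assert classify_mobility(curve, 40) == "immobile"
    assert classify_trajectory(still, null_160_40).mode == "immobile"

    moving = simulate_trajectory(
        SimulationConfig(mode="free", D_micro=3.0, delta_t=5e-4, n_frames=160,
                         substeps=1, loc_sigma=0.02), seed=9, track_id="m")
    assert classify_mobility(
        estimate_noise_floor(compute_msd(moving, max_lag=40)), 40) == "mobile"


def test_immobile_fraction_small_in_lipid_like_regime(null_160_40):
    cfg = SimulationConfig(mode="free", D_micro=0.5, delta_t=5e-4, n_frames=160,
                           substeps=1, loc_sigma=0.02, n_traj=300, seed=404)
    results, _ = classify_tracks(simulate_ensemble(cfg), null_160_40)
    immobile = np.mean([r.mode == "immobile" for r in results])
    assert immobile <= 0.05


def test_hop_tracks_with_strong_barriers_classify_suppressed(null_160_40):
    # Compartments comparable to the length explored per few frames and a low
    # crossing probability make the long-lag MSD fall far below 4·D_2-4·nδt.
    cfg = SimulationConfig(mode="hop", D_micro=5.0, compartment=(0.3, 0.3),
                           p_hop=0.005, delta_t=5e-4, n_frames=160, substeps=16,
                           loc_sigma=0.0, n_traj=80, seed=505)
    results, _ = classify_tracks(simulate_ensemble(cfg), null_160_40)
    modes = [r.mode for r in results]
    assert np.mean([m == "suppressed" for m in modes]) > 0.5


def test_drift_dominated_tracks_classify_directed(null_160_40):
    cfg = SimulationConfig(mode="directed", D_micro=0.5, drift=(20.0, 0.0),
                           delta_t=5e-4, n_frames=160, substeps=1,
                           loc_sigma=0.0, n_traj=60, seed=606)
    results, _ = classify_tracks(simulate_ensemble(cfg), null_160_40)
    assert np.mean([r.mode == "directed" for r in results]) > 0.5


def test_suppressed_detection_rate_decreases_towards_free(null_160_40):
    rates = []
    for p in (0.005, 0.2, 1.0):
        cfg = SimulationConfig(mode="hop", D_micro=5.0, compartment=(0.3, 0.3),
                               p_hop=p, delta_t=5e-4, n_frames=160, substeps=16,
                               loc_sigma=0.0, n_traj=60, seed=707)
        results, _ = classify_tracks(simulate_ensemble(cfg), null_160_40)
        rates.append(np.mean([r.mode == "suppressed" for r in results]))
    assert rates[0] > rates[1] >= rates[2]
    assert rates[2] < 0.2


def test_short_tracks_are_skipped_with_reason(null_160_40):
    short = simulate_trajectory(
        SimulationConfig(mode="free", D_micro=1.0, delta_t=5e-4, n_frames=100,
                         substeps=1, loc_sigma=0.0), seed=1, track_id="short")
    with pytest.raises(TrackTooShortError):
        classify_trajectory(short, null_160_40)
    _, skipped = classify_tracks([short], null_160_40)
    assert skipped and skipped[0][0] == "short"


def test_long_tracks_use_leading_n_frames(null_160_40):
    long_tr = simulate_trajectory(
        SimulationConfig(mode="free", D_micro=1.0, delta_t=5e-4, n_frames=400,
                         substeps=1, loc_sigma=0.0), seed=2, track_id="long")
    r_long = classify_trajectory(long_tr, null_160_40)
    r_head = classify_trajectory(long_tr.head(160), null_160_40)
    assert r_long.rd == pytest.approx(r_head.rd, rel=1e-12)


def test_fraction_simple_edge_cases():
    mk = lambda mode: ModeResult("t", 1.0, mode, 160, 40, 5e-4, 1.0)
    assert fraction_simple([mk("simple")] * 5) == 1.0
    with pytest.warns(UserWarning, match="immobile"):
        assert np.isnan(fraction_simple([mk("immobile")] * 3))
    with pytest.raises(ValueError):
        fraction_simple([])
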
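"""Diffusion-mode classification with the RD statistic.

Each mobile track is scored by the relative deviation of its long-term MSD
from the simple-Brownian expectation built on its own short-lag diffusion
coefficient::

    RD(N, n) = MSD(n·δt) / (4 · D_2-4 · n·δt)

RD scatters around 1 for simple Brownian motion, falls below 1 for
suppressed (confined / hop) diffusion and rises above 1 for directed motion.
Because single-track RD fluctuates strongly, the cutoffs are calibrated on a
Monte Carlo null: the 2.5th and 97.5th percentiles (RD_min, RD_MAX) of RD
over simulated ideal Brownian tracks of the same (N, n, δt).  By design 95%
of ideal Brownian tracks classify as simple.

The null is simulated without localization noise, and every track — null or
experimental — goes through the identical MSD(0)-subtraction pipeline before
RD is formed, so the thresholds calibrate the corrected statistic.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Iterable, Sequence
import warnings

import numpy as np

from .simulate import SimulationConfig, Trajectory, simulate_ensemble
from .msd import MSDCurve, compute_msd, estimate_noise_floor, estimate_D24

__all__ = [
    "RDNull",
    "ModeResult",
    "UndefinedRDError",
    "TrackTooShortError",
    "rd_statistic",
    "build_rd_null",
    "classify_mobility",
    "classify_trajectory",
    "classify_tracks",
    "fraction_simple",
]

#: Multiple of the noise floor below which a track counts as immobile.
DEFAULT_IMMOBILE_K = 2.0


class UndefinedRDError(ValueError):
    """RD is undefined because D_2-4 <= 0 (track routed to the immobile check)."""


class TrackTooShortError(ValueError):
    """Track shorter than the N frames the null was calibrated for."""


@dataclass
class RDNull:
    """Simulated null distribution of RD(N, n) for fixed (N, n, δt)."""

    N: int
    n: int
    delta_t: float
    n_sims: int
    rd_values: np.ndarray
    rd_min: float
    rd_max: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        d = {
            "N": self.N, "n": self.n, "delta_t": self.delta_t,
            "n_sims": self.n_sims, "rd_min": self.rd_min, "rd_max": self.rd_max,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(d, indent=2))


@dataclass
class ModeResult:
    """Per-track classification outcome."""

    track_id: str
    rd: float            # recorded even when immobile (NaN if D_2-4 <= 0)
    mode: str            # immobile | suppressed | simple | directed
    N: int
    n: int
    delta_t: float
    D24: float           # µm²/s


def _rd_from_curve(curve: MSDCurve, n: int) -> tuple[float, float]:
    """(RD, D24) from a noise-corrected curve; RD NaN when D24 <= 0."""
    if not curve.noise_estimated:
        curve = estimate_noise_floor(curve)
    if n > len(curve):
        raise ValueError(f"lag n={n} exceeds the {len(curve)} lags of the curve")
    d24 = estimate_D24(curve)
    if d24 <= 0:
        return float("nan"), d24
    rd = curve.msd[n - 1] / (4.0 * d24 * n * curve.delta_t_frame)
    return float(rd), d24


def rd_statistic(curve: MSDCurve, n: int) -> float:
    """RD(N, n) of one curve; raises :class:`UndefinedRDError` if D_2-4 <= 0."""
    rd, d24 = _rd_from_curve(curve, n)
    if d24 <= 0:
        raise UndefinedRDError(
            f"track {curve.track_id!r}: D_2-4 = {d24:.3g} <= 0, RD undefined"
        )
    return rd


def build_rd_null(
    N: int,
    n: int,
    delta_t: float,
    n_sims: int = 10_000,
    seed: int = 0,
    D: float = 1.0,
) -> RDNull:
    """Calibrate RD_min / RD_MAX on simulated ideal Brownian tracks.

    RD is scale-free, so the diffusion coefficient used for the null is
    immaterial; tracks are simulated noise-free and run through the same
    correction pipeline as experimental curves.  Percentiles use linear
    interpolation.
    """
    if n_sims < 1000:
        raise ValueError(f"n_sims must be >= 1000, got {n_sims}")
    if not 4 <= n <= N - 1:
        raise ValueError(f"need 4 <= n <= N-1, got n={n}, N={N}")
    cfg = SimulationConfig(
        mode="free", D_micro=D, delta_t=delta_t, n_frames=N,
        substeps=1, loc_sigma=0.0, n_traj=n_sims, seed=seed,
    )
    rd = np.empty(n_sims)
    for i, traj in enumerate(simulate_ensemble(cfg)):
        curve = estimate_noise_floor(compute_msd(traj, max_lag=n))
        rd[i], _ = _rd_from_curve(curve, n)
    rd = rd[np.isfinite(rd)]
    rd_min, rd_max = np.percentile(rd, [2.5, 97.5])
    return RDNull(N, n, delta_t, n_sims, rd, float(rd_min), float(rd_max), seed)


def classify_mobility(
    curve: MSDCurve, n: int, k: float = DEFAULT_IMMOBILE_K
) -> str:
    """``"mobile"`` or ``"immobile"``.

    A track is immobile when its corrected MSD at the classification lag does
    not exceed ``k`` times the noise floor, or when D_2-4 <= 0.
    """
    if not curve.noise_estimated:
        curve = estimate_noise_floor(curve)
    d24 = estimate_D24(curve)
    if d24 <= 0:
        return "immobile"
    if curve.msd[n - 1] <= k * curve.noise_floor:
        return "immobile"
    return "mobile"


def classify_trajectory(
    traj: Trajectory | MSDCurve,
    null: RDNull,
    k_immobile: float = DEFAULT_IMMOBILE_K,
) -> ModeResult:
    """Classify one track against a calibrated RD null.

    Longer tracks contribute only their leading N frames (one RD per track);
    shorter tracks raise :class:`TrackTooShortError`.  The immobile pre-filter
    runs first; mobile tracks are suppressed if RD < RD_min, directed if
    RD > RD_MAX, else simple.
    """
    if isinstance(traj, MSDCurve):
        curve = traj
        if curve.N != null.N:
            raise TrackTooShortError(
                f"curve {curve.track_id!r} covers N={curve.N} frames; null expects N={null.N}"
            )
    else:
        if len(traj) < null.N:
            raise TrackTooShortError(
                f"track {traj.track_id!r} has {len(traj)} < N={null.N} frames"
            )
        curve = compute_msd(traj.head(null.N), max_lag=null.n)
    if not curve.noise_estimated:
        curve = estimate_noise_floor(curve)
    rd, d24 = _rd_from_curve(curve, null.n)
    mobility = classify_mobility(curve, null.n, k=k_immobile)
    if mobility == "immobile":
        mode = "immobile"
    elif rd < null.rd_min:
        mode = "suppressed"
    elif rd > null.rd_max:
        mode = "directed"
    else:
        mode = "simple"
    return ModeResult(
        track_id=curve.track_id, rd=rd, mode=mode,
        N=null.N, n=null.n, delta_t=null.delta_t, D24=d24,
    )


def classify_tracks(
    trajs: Iterable[Trajectory],
    null: RDNull,
    k_immobile: float = DEFAULT_IMMOBILE_K,
) -> tuple[list[ModeResult], list[tuple[str, str]]]:
    """Classify many tracks; returns (results, skipped) where each skipped
    entry is ``(track_id, reason)``."""
    results: list[ModeResult] = []
    skipped: list[tuple[str, str]] = []
    for traj in trajs:
        try:
            results.append(classify_trajectory(traj, null, k_immobile=k_immobile))
        except TrackTooShortError as exc:
            skipped.append((traj.track_id, str(exc)))
    return results, skipped


def fraction_simple(results: Sequence[ModeResult]) -> float:
    """Fraction of mobile tracks classified simple-Brownian.

    NaN (with a warning) when no track is mobile.
    """
    if len(results) == 0:
        raise ValueError("fraction_simple requires at least one result")
    mobile = [r for r in results if r.mode != "immobile"]
    if not mobile:
        warnings.warn("all tracks immobile; simple fraction undefined", stacklevel=2)
        return float("nan")
    return sum(r.mode == "simple" for r in mobile) / len(mobile)
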
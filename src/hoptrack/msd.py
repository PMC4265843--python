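"""Time-averaged mean-square displacement (MSD) and short-lag diffusion estimates.

The MSD of a track with P recorded positions at lag ``n`` averages all P − n
overlapping displacement pairs::

    MSD(n·δt) = mean_j [ (x(jδt + nδt) − x(jδt))² + (y(jδt + nδt) − y(jδt))² ]

Static localization noise adds a constant offset to every lag (2σ² per
coordinate).  That noise floor, MSD(0), is estimated as the intercept of an
ordinary least-squares line through the MSD values at lags 2δt, 3δt and 4δt and
subtracted from the curve; the short-lag diffusion coefficient D_2-4 is the
slope of the same line divided by 4 (by 2 for single-axis curves) and is
therefore unaffected by the subtraction.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .simulate import Trajectory

__all__ = [
    "MSDCurve",
    "EnsembleMSD",
    "compute_msd",
    "estimate_noise_floor",
    "estimate_D24",
    "ensemble_msd",
]


@dataclass
class MSDCurve:
    """Time-averaged MSD of one track at lags 1..max_lag.

    ``msd`` holds the noise-subtracted values once
    :func:`estimate_noise_floor` has run; until then it equals ``msd_raw``.
    Negative corrected values are recorded, never clipped.
    """

    lag_time: np.ndarray        # n * delta_t_frame, s
    msd_raw: np.ndarray         # µm²
    n_pairs: np.ndarray         # displacement pairs averaged per lag
    N: int                      # track length in frames (recorded positions)
    delta_t_frame: float        # s
    track_id: str = ""
    axis: str = "xy"            # "xy", "x" or "y"
    noise_floor: float = 0.0    # MSD(0), µm²
    msd: np.ndarray = field(default=None)  # type: ignore[assignment]
    noise_estimated: bool = False

    def __post_init__(self) -> None:
        if self.msd is None:
            self.msd = np.array(self.msd_raw, copy=True)

    @property
    def lags(self) -> np.ndarray:
        return np.arange(1, self.msd_raw.size + 1)

    def __len__(self) -> int:
        return self.msd_raw.size


def compute_msd(traj: Trajectory, max_lag: int | None = None, axis: str = "xy") -> MSDCurve:
    """Time-averaged MSD over all overlapping windows.

    Parameters
    ----------
    traj:
        Input track (>= 2 frames).
    max_lag:
        Largest lag in frames; defaults to N − 1.
    axis:
        ``"xy"`` for the 2D MSD, ``"x"``/``"y"`` for a single-coordinate MSD
        (used by per-axis hop-diffusion fitting).
    """
    N = len(traj)
    if N < 2:
        raise ValueError(f"track {traj.track_id!r}: need at least 2 frames, got {N}")
    if max_lag is None:
        max_lag = N - 1
    if not 1 <= max_lag <= N - 1:
        raise ValueError(f"max_lag must lie in [1, N-1] = [1, {N - 1}], got {max_lag}")
    if axis == "xy":
        pos = np.column_stack([traj.x, traj.y])
    elif axis == "x":
        pos = traj.x[:, None]
    elif axis == "y":
        pos = traj.y[:, None]
    else:
        raise ValueError(f"axis must be 'xy', 'x' or 'y', got {axis!r}")

    msd = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=int)
    for n in range(1, max_lag + 1):
        d = pos[n:] - pos[:-n]
        msd[n - 1] = np.mean(np.sum(d * d, axis=1))
        n_pairs[n - 1] = N - n
    return MSDCurve(
        lag_time=np.arange(1, max_lag + 1) * traj.delta_t,
        msd_raw=msd,
        n_pairs=n_pairs,
        N=N,
        delta_t_frame=traj.delta_t,
        track_id=traj.track_id,
        axis=axis,
    )


def _fit_lags_2_4(curve: MSDCurve) -> tuple[float, float]:
    """(slope, intercept) of the OLS line through the lag-2..4 raw MSD points."""
    if len(curve) < 4:
        raise ValueError(
            f"track {curve.track_id!r}: need MSD at lags 2-4 (>= 4 lags), got {len(curve)}"
        )
    x = curve.lag_time[1:4]
    y = curve.msd_raw[1:4]
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def estimate_noise_floor(curve: MSDCurve) -> MSDCurve:
    """Estimate MSD(0) and return a curve with noise-subtracted values.

    MSD(0) is the y-intercept of the straight line fitted through MSD(2δt),
    MSD(3δt) and MSD(4δt).  The corrected curve may go negative for
    noise-dominated tracks; values are recorded as-is.
    """
    _, intercept = _fit_lags_2_4(curve)
    return dataclasses.replace(
        curve,
        noise_floor=intercept,
        msd=curve.msd_raw - intercept,
        noise_estimated=True,
    )


def estimate_D24(curve: MSDCurve) -> float:
    """Short-lag diffusion coefficient D_2-4, µm²/s.

    Slope of the lag-2..4 line divided by 4 for 2D curves (2 for per-axis
    curves).  The slope of the raw curve is used; the MSD(0) subtraction
    shifts the intercept only.  May be <= 0 for noise-dominated tracks;
    callers treat that as a non-positive-D flag.
    """
    slope, _ = _fit_lags_2_4(curve)
    return slope / (4.0 if curve.axis == "xy" else 2.0)


@dataclass
class EnsembleMSD:
    """Per-lag mean and SE of a set of MSD curves, with a linearity check."""

    lag_time: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_tracks: int
    slope: float
    intercept: float
    p_linear: float  # chi-square tail probability of WLS residuals vs per-lag SE


def ensemble_msd(curves: Sequence[MSDCurve], max_lag: int | None = None) -> EnsembleMSD:
    """Ensemble-averaged MSD across trajectories.

    The per-lag mean and standard error are taken across tracks; a weighted
    least-squares line is fitted and its goodness reported as the chi-square
    tail probability of the residuals against the per-lag SE.  With a single
    curve the SE is zero-flagged and the p-value undefined (NaN).
    """
    if len(curves) == 0:
        raise ValueError("ensemble_msd requires at least one curve")
    dt = curves[0].delta_t_frame
    ax = curves[0].axis
    for c in curves:
        if not np.isclose(c.delta_t_frame, dt):
            raise ValueError("curves do not share a frame interval")
        if c.axis != ax:
            raise ValueError("curves mix axes")
    if max_lag is None:
        max_lag = min(len(c) for c in curves)
    stack = np.vstack([c.msd[:max_lag] for c in curves])
    lag_time = np.arange(1, max_lag + 1) * dt
    mean = stack.mean(axis=0)
    m = stack.shape[0]
    if m < 2:
        se = np.zeros(max_lag)
        slope, intercept = np.polyfit(lag_time, mean, 1)
        return EnsembleMSD(lag_time, mean, se, m, float(slope), float(intercept), float("nan"))
    se = stack.std(axis=0, ddof=1) / np.sqrt(m)
    w = 1.0 / np.maximum(se, 1e-300) ** 2
    slope, intercept = np.polyfit(lag_time, mean, 1, w=np.sqrt(w))
    resid = mean - (slope * lag_time + intercept)
    chi2 = float(np.sum(w * resid**2))
    dof = max(max_lag - 2, 1)
    p = float(stats.chi2.sf(chi2, dof))
    return EnsembleMSD(lag_time, mean, se, m, float(slope), float(intercept), p)
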
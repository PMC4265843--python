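"""Transient-confinement-zone detection (sliding-window escape probability).

For each window of ``window`` consecutive frames the maximal displacement R
from the window's first point is measured, and the probability psi that a
free Brownian particle with reference coefficient ``D_ref`` would stay
within R for the window duration is evaluated with the log-linear
approximation

    log10(psi) = 0.2048 − 2.5117 · (D_ref · t / R²)

The confinement index is the positive part of −log10(psi) − 1: zero for
typical free-diffusion windows, large when the particle dwells in a region
much smaller than free diffusion would explore.  Runs of supra-threshold
index lasting at least a minimum duration are reported as confinement
segments.

R is floored at the localization accuracy so a pinned particle yields a
large but finite index.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .simulate import Trajectory

__all__ = [
    "ConfinementProfile",
    "ConfinementSegment",
    "confinement_index",
    "detect_confinement_segments",
    "SIMSON_INTERCEPT",
    "SIMSON_SLOPE",
]

# Constants of the log-linear staying-probability approximation.
SIMSON_INTERCEPT = 0.2048
SIMSON_SLOPE = 2.5117

#: Defaults calibrated on simulated free diffusion so that the per-track
#: false-positive segment rate stays below 5% while 20 ms traps in an 85 nm
#: zone are still detected with >80% sensitivity at 0.5 ms frame time
#: (see tests).
DEFAULT_WINDOW = 16
DEFAULT_THRESHOLD = 2.0
DEFAULT_MIN_DURATION = 0.004  # s


@dataclass
class ConfinementSegment:
    start_frame: int
    end_frame: int      # inclusive
    duration: float     # s
    max_index: float


@dataclass
class ConfinementProfile:
    """Per-frame confinement-probability index of one track.

    ``index[i]`` is the index of the window starting at frame ``i``; frames
    where no full window fits hold NaN.
    """

    track_id: str
    window: int
    delta_t: float
    index: np.ndarray
    D_ref: float
    loc_sigma: float


def confinement_index(
    traj: Trajectory,
    window: int = DEFAULT_WINDOW,
    D_ref: float | None = None,
    loc_sigma: float = 0.02,
) -> ConfinementProfile:
    """Sliding-window confinement index of one track.

    Parameters
    ----------
    traj:
        Input track.
    window:
        Window length in frames (>= 4).
    D_ref:
        Reference free-diffusion coefficient, µm²/s — typically the track's
        own D_2-4 or an ensemble value.  Defaults to the track's D_2-4.
    loc_sigma:
        Localization accuracy, µm; floors the maximal displacement R.
    """
    P = len(traj)
    if window < 4:
        raise ValueError(f"window must be >= 4 frames, got {window}")
    if window > P:
        raise ValueError(
            f"track {traj.track_id!r}: window of {window} frames exceeds track length {P}"
        )
    if D_ref is None:
        from .msd import compute_msd, estimate_D24

        D_ref = estimate_D24(compute_msd(traj, max_lag=min(4, P - 1)))
    if D_ref <= 0:
        raise ValueError(f"D_ref must be > 0, got {D_ref}")

    sw_x = np.lib.stride_tricks.sliding_window_view(traj.x, window)
    sw_y = np.lib.stride_tricks.sliding_window_view(traj.y, window)
    dx = sw_x - sw_x[:, :1]
    dy = sw_y - sw_y[:, :1]
    r2 = np.max(dx * dx + dy * dy, axis=1)
    r2 = np.maximum(r2, loc_sigma**2)
    t_win = (window - 1) * traj.delta_t
    log10_psi = SIMSON_INTERCEPT - SIMSON_SLOPE * D_ref * t_win / r2
    idx = np.maximum(-log10_psi - 1.0, 0.0)
    index = np.full(P, np.nan)
    index[: idx.size] = idx
    return ConfinementProfile(
        track_id=traj.track_id, window=window, delta_t=traj.delta_t,
        index=index, D_ref=float(D_ref), loc_sigma=loc_sigma,
    )


def detect_confinement_segments(
    profile: ConfinementProfile,
    threshold: float = DEFAULT_THRESHOLD,
    min_duration: float = DEFAULT_MIN_DURATION,
) -> list[ConfinementSegment]:
    """Maximal supra-threshold runs of the index lasting >= ``min_duration``.

    Segment frame ranges refer to window start frames; duration is the run
    length times the frame interval.
    """
    above = np.nan_to_num(profile.index, nan=-np.inf) >= threshold
    segments: list[ConfinementSegment] = []
    i = 0
    P = above.size
    while i < P:
        if above[i]:
            j = i
            while j + 1 < P and above[j + 1]:
                j += 1
            duration = (j - i + 1) * profile.delta_t
            if duration >= min_duration:
                segments.append(
                    ConfinementSegment(
                        start_frame=i, end_frame=j, duration=duration,
                        max_index=float(np.nanmax(profile.index[i : j + 1])),
                    )
                )
            i = j + 1
        else:
            i += 1
    return segments
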
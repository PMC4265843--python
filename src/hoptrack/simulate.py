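"""Monte Carlo generator of 2D single-particle trajectories.

Four motion models are supported, covering the regimes a membrane
single-particle-tracking analysis has to distinguish:

``free``
    Unobstructed Brownian motion with diffusion coefficient ``D_micro``.
``directed``
    Brownian motion superimposed on a constant drift velocity.
``confined``
    Brownian motion inside a single rectangular compartment with
    perfectly reflecting walls.
``hop``
    Picket-fence (hop) diffusion: Brownian motion on a regular lattice of
    semipermeable barriers with spacing ``(L_x, L_y)``.  A substep that
    crosses a barrier line succeeds with probability ``p_hop`` and is
    otherwise reflected about that line.

Dynamics are integrated with Gaussian substeps of variance
``2 * D_micro * delta_t / substeps`` per coordinate; frame positions are the
substep positions at frame boundaries, plus i.i.d. Gaussian localization
noise added at sampling only (measurement noise never feeds back into the
dynamics).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MODES",
    "RNG_ALGORITHM",
    "ConfigurationError",
    "SimulationConfig",
    "Trajectory",
    "simulate_trajectory",
    "simulate_ensemble",
    "estimate_dmacro",
    "calibrate_p_hop",
]

MODES = ("free", "directed", "confined", "hop")

#: How per-trajectory random streams are derived, recorded in output metadata.
RNG_ALGORITHM = "numpy PCG64; per-trajectory streams via SeedSequence(seed).spawn"


class ConfigurationError(ValueError):
    """Raised when a :class:`SimulationConfig` violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative specification of a simulated ensemble.

    Parameters
    ----------
    mode:
        One of ``free``, ``directed``, ``confined``, ``hop``.
    D_micro:
        Microscopic diffusion coefficient within a compartment, µm²/s.
    drift:
        Drift velocity ``(v_x, v_y)`` in µm/s; used by ``directed`` mode only.
    compartment:
        Compartment dimensions ``(L_x, L_y)`` in µm; used by ``confined`` and
        ``hop`` modes.
    p_hop:
        Probability that a substep crossing a barrier line is allowed through,
        per crossing attempt (dimensionless, in [0, 1]).
    delta_t:
        Frame interval in seconds.
    n_frames:
        Recorded positions per trajectory.
    substeps:
        Simulation substeps per frame interval.
    loc_sigma:
        Localization noise SD per coordinate, µm.
    n_traj:
        Trajectories per ensemble.
    seed:
        Master RNG seed for the ensemble.
    """

    mode: str
    D_micro: float = 5.0
    drift: tuple[float, float] = (0.0, 0.0)
    compartment: tuple[float, float] = (0.085, 0.085)
    p_hop: float = 1.0
    delta_t: float = 2e-5
    n_frames: int = 2500
    substeps: int = 4
    loc_sigma: float = 0.019
    n_traj: int = 100
    seed: int = 0

    def substep_rms(self) -> float:
        """RMS substep displacement per coordinate, µm."""
        return math.sqrt(2.0 * self.D_micro * self.delta_t / self.substeps)

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.D_micro < 0:
            raise ConfigurationError(f"D_micro must be >= 0, got {self.D_micro}")
        if not 0.0 <= self.p_hop <= 1.0:
            raise ConfigurationError(f"p_hop must lie in [0, 1], got {self.p_hop}")
        if self.substeps < 1:
            raise ConfigurationError(f"substeps must be >= 1, got {self.substeps}")
        if self.n_frames < 2:
            raise ConfigurationError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.loc_sigma < 0:
            raise ConfigurationError(f"loc_sigma must be >= 0, got {self.loc_sigma}")
        if self.delta_t <= 0:
            raise ConfigurationError(f"delta_t must be > 0, got {self.delta_t}")
        if self.n_traj < 1:
            raise ConfigurationError(f"n_traj must be >= 1, got {self.n_traj}")
        if self.mode in ("confined", "hop"):
            lx, ly = self.compartment
            if lx <= 0 or ly <= 0:
                raise ConfigurationError(f"compartment sides must be > 0, got {self.compartment}")
            lmin = min(lx, ly)
            rms = self.substep_rms()
            if rms > lmin / 10.0:
                raise ConfigurationError(
                    "substep RMS displacement too large for the compartment: "
                    f"sqrt(2*D_micro*delta_t/substeps) = {rms:.3e} µm exceeds "
                    f"min(L_x, L_y)/10 = {lmin / 10.0:.3e} µm "
                    f"(ratio {rms / (lmin / 10.0):.2f}); increase substeps"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drift"] = list(self.drift)
        d["compartment"] = list(self.compartment)
        d["rng"] = RNG_ALGORITHM
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d.pop("rng", None)
        if "drift" in d:
            d["drift"] = tuple(d["drift"])
        if "compartment" in d:
            d["compartment"] = tuple(d["compartment"])
        return cls(**d)


@dataclass
class Trajectory:
    """A single 2D track sampled at a uniform frame interval.

    Times are seconds, positions µm.  ``truth`` optionally carries the
    generating :class:`SimulationConfig` for simulated data.
    """

    track_id: str
    delta_t: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    truth: Optional[SimulationConfig] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.size == self.x.size == self.y.size) or self.t.size < 2:
            raise ValueError(
                f"track {self.track_id!r}: t/x/y must have equal length >= 2"
            )
        steps = np.diff(self.t)
        if not np.allclose(steps, self.delta_t, rtol=1e-6, atol=1e-12):
            raise ValueError(
                f"track {self.track_id!r}: frame times are not uniform at delta_t={self.delta_t}"
            )

    def __len__(self) -> int:
        return self.t.size

    def head(self, n_frames: int) -> "Trajectory":
        """First ``n_frames`` positions as a new trajectory."""
        if n_frames > len(self):
            raise ValueError(f"track {self.track_id!r} has {len(self)} < {n_frames} frames")
        return Trajectory(
            self.track_id, self.delta_t,
            self.t[:n_frames], self.x[:n_frames], self.y[:n_frames], self.truth,
        )


def _reflect_fold(x: np.ndarray, L: float) -> np.ndarray:
    # Reflecting boundaries on [0, L] are equivalent to folding the free path
    # with period 2L (exact, for any sequence of increments).
    y = np.mod(x, 2.0 * L)
    return np.where(y > L, 2.0 * L - y, y)


def _hop_axis(x0: float, dx: np.ndarray, u: np.ndarray, L: float, p: float) -> np.ndarray:
    """Sequential 1D walk on a lattice of semipermeable barriers at multiples of L.

    Each substep that would cross the current compartment's wall passes with
    probability ``p`` and is otherwise reflected about the wall.  The substep
    invariant (RMS step <= L/10) makes multiple barrier events per substep
    vanishingly rare; when they do occur the same uniform draw is reused.
    """
    n = dx.size
    out = np.empty(n + 1)
    out[0] = x = float(x0)
    lo = math.floor(x / L) * L
    hi = lo + L
    dxl = dx.tolist()
    ul = u.tolist()
    for i in range(n):
        nx = x + dxl[i]
        while nx < lo or nx > hi:
            if nx < lo:
                if ul[i] < p:
                    lo -= L
                    hi -= L
                else:
                    nx = 2.0 * lo - nx
            else:
                if ul[i] < p:
                    lo += L
                    hi += L
                else:
                    nx = 2.0 * hi - nx
        x = nx
        out[i + 1] = x
    return out


def simulate_trajectory(
    config: SimulationConfig,
    seed: int | np.random.SeedSequence,
    track_id: str = "sim-0000",
) -> Trajectory:
    """Generate one trajectory under ``config`` using the given seed.

    Identical ``(config, seed)`` pairs give bitwise-identical output.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    P = config.n_frames
    s = config.substeps
    M = (P - 1) * s
    dt_sub = config.delta_t / s
    scale = math.sqrt(2.0 * config.D_micro * dt_sub)

    if config.mode in ("free", "directed"):
        steps = rng.normal(0.0, scale, size=(M, 2)) if scale > 0 else np.zeros((M, 2))
        path = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        if config.mode == "directed":
            t_sub = np.arange(M + 1) * dt_sub
            path = path + np.outer(t_sub, np.asarray(config.drift, dtype=float))
    elif config.mode == "confined":
        lx, ly = config.compartment
        x0 = rng.uniform(0.0, lx)
        y0 = rng.uniform(0.0, ly)
        steps = rng.normal(0.0, scale, size=(M, 2)) if scale > 0 else np.zeros((M, 2))
        freepath = np.vstack([[x0, y0], [x0, y0] + np.cumsum(steps, axis=0)])
        path = np.column_stack(
            [_reflect_fold(freepath[:, 0], lx), _reflect_fold(freepath[:, 1], ly)]
        )
    else:  # hop
        lx, ly = config.compartment
        x0 = rng.uniform(0.0, lx)
        y0 = rng.uniform(0.0, ly)
        steps = rng.normal(0.0, scale, size=(M, 2)) if scale > 0 else np.zeros((M, 2))
        u = rng.uniform(size=(M, 2))
        if config.p_hop >= 1.0:
            # Fully permeable barriers: identical in law to free diffusion.
            path = np.vstack([[x0, y0], [x0, y0] + np.cumsum(steps, axis=0)])
        else:
            path = np.column_stack(
                [
                    _hop_axis(x0, steps[:, 0], u[:, 0], lx, config.p_hop),
                    _hop_axis(y0, steps[:, 1], u[:, 1], ly, config.p_hop),
                ]
            )

    frames = path[::s]
    if config.loc_sigma > 0:
        frames = frames + rng.normal(0.0, config.loc_sigma, size=frames.shape)
    t = np.arange(P) * config.delta_t
    return Trajectory(track_id, config.delta_t, t, frames[:, 0], frames[:, 1], truth=config)


def simulate_ensemble(config: SimulationConfig) -> list[Trajectory]:
    """Generate ``config.n_traj`` mutually independent trajectories.

    Per-trajectory streams are spawned from ``config.seed`` with numpy's
    SeedSequence, so the ensemble is reproducible from the config alone.
    """
    config.validate()
    children = np.random.SeedSequence(config.seed).spawn(config.n_traj)
    return [
        simulate_trajectory(config, child, track_id=f"sim-{i:04d}")
        for i, child in enumerate(children)
    ]


def estimate_dmacro(
    trajs: Sequence[Trajectory],
    max_lag: int | None = None,
    fit_window: tuple[float, float] = (0.5, 1.0),
) -> float:
    """Long-lag (macroscopic) 2D diffusion coefficient of an ensemble, µm²/s.

    Slope/4 of a least-squares line through the ensemble-mean time-averaged
    MSD over the lag window ``fit_window`` (fractions of ``max_lag``),
    weighted by the inverse squared per-lag SE when the ensemble allows it.
    Intended for noise-free simulated ensembles, e.g. inside
    :func:`calibrate_p_hop`.
    """
    from .msd import compute_msd, ensemble_msd

    if max_lag is None:
        # long lags of the time average are very noisy; stop at a quarter
        # of the track length
        max_lag = max((min(len(tr) for tr in trajs) - 1) // 4, 2)
    curves = [compute_msd(tr, max_lag=max_lag) for tr in trajs]
    ens = ensemble_msd(curves, max_lag=max_lag)
    lo = max(1, int(fit_window[0] * max_lag))
    hi = int(fit_window[1] * max_lag)
    sel = slice(lo - 1, hi)
    if len(trajs) > 1:
        w = 1.0 / np.maximum(ens.se[sel], 1e-300)
        slope = np.polyfit(ens.lag_time[sel], ens.mean[sel], 1, w=w)[0]
    else:
        slope = np.polyfit(ens.lag_time[sel], ens.mean[sel], 1)[0]
    return slope / 4.0


def calibrate_p_hop(
    config: SimulationConfig,
    target_dmacro: float,
    *,
    n_traj: int = 128,
    n_frames: int = 800,
    rel_tol: float = 0.03,
    max_iter: int = 14,
) -> tuple[float, float]:
    """Tune ``p_hop`` by bisection so the emergent long-lag D matches a target.

    The per-attempt crossing probability is a microscopic parameter whose
    macroscopic effect depends on the substep size, so observed D ratios are
    mapped to ``p_hop`` empirically: each candidate is evaluated on a
    noise-free hop ensemble (common random numbers across iterations) and the
    emergent :func:`estimate_dmacro` is compared with ``target_dmacro``.

    Returns ``(p_hop, achieved_dmacro)``.
    """
    if not 0 < target_dmacro <= config.D_micro:
        raise ConfigurationError(
            f"target D_MACRO must lie in (0, D_micro={config.D_micro}], got {target_dmacro}"
        )

    def emergent(p: float) -> float:
        cfg = replace(
            config, mode="hop", p_hop=p, loc_sigma=0.0,
            n_traj=n_traj, n_frames=n_frames,
        )
        return estimate_dmacro(simulate_ensemble(cfg))

    lo, hi = -5.0, 0.0  # log10 p bracket
    d_hi = emergent(1.0)
    if target_dmacro >= d_hi:
        return 1.0, d_hi
    p = 1.0
    d = d_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p = 10.0 ** mid
        d = emergent(p)
        if abs(d - target_dmacro) <= rel_tol * target_dmacro:
            break
        if d < target_dmacro:
            lo = mid
        else:
            hi = mid
    return p, d
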
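"""Theoretical MSD models and hop-diffusion fitting.

Models
------
``directed_msd_model``
    2D MSD of drift plus diffusion, ``4Dt + |v|² t²``.
``confined_msd_model``
    Exact 1D MSD for Brownian motion between reflecting walls spaced ``L``
    apart, starting from the uniform (stationary) distribution::

        MSD(t) = L²/6 − (16 L²/π⁴) Σ_{k odd} k⁻⁴ exp(−(kπ/L)² D t)

    with free-diffusion slope ``2Dt`` as t → 0 and asymptote ``L²/6``.
``hop_msd_model``
    Exact 1D MSD for diffusion through an infinite periodic array of
    semipermeable barriers with spacing ``L`` and membrane permeability κ,
    from a uniform start.  The three user-facing parameters map onto the
    barrier model through the series-resistance relation

        D_MACRO = D_micro · κL / (κL + D_micro)

    so that the t → 0 slope is ``2 D_micro`` and the long-time behaviour is
    ``2 D_MACRO t + const``.  The Laplace transform of the MSD is obtained in
    closed form (transfer-matrix impedance of the semi-infinite barrier
    lattice) and inverted numerically on a fixed Talbot contour; the result
    reduces to free diffusion at D_MACRO = D_micro, to the confined model at
    D_MACRO = 0, and is certified against the hop-mode Monte Carlo simulator
    (see the package test suite).

Fitting
-------
``fit_hop`` fits the hop model to the per-axis MSD curves of one track by
weighted nonlinear least squares, returning per-axis barrier spacings, their
geometric mean (the compartment size, reported as √(LxLy)), D_micro, D_MACRO
and the residency time L²/(4 D_MACRO).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .msd import MSDCurve, estimate_noise_floor, estimate_D24, _fit_lags_2_4

__all__ = [
    "HopFitResult",
    "directed_msd_model",
    "confined_msd_model",
    "hop_msd_model",
    "fit_hop",
    "residency_time",
]

#: D_MACRO/D_micro ratio above which a track is declared unresolvable
#: (indistinguishable from free diffusion on the fitted window).
FREE_LIKE_RATIO = 0.9


def directed_msd_model(t, D: float, v: tuple[float, float]) -> np.ndarray:
    """2D MSD for Brownian motion with constant drift: 4Dt + (vx²+vy²) t²."""
    t = np.asarray(t, dtype=float)
    v2 = float(v[0]) ** 2 + float(v[1]) ** 2
    return 4.0 * D * t + v2 * t * t


def confined_msd_model(t, L: float, D_micro: float, rtol: float = 1e-6) -> np.ndarray:
    """Exact 1D MSD for reflecting-wall confinement from a uniform start.

    The eigenfunction series is truncated adaptively so the relative
    truncation error is below ``rtol`` at every requested time.
    """
    if L <= 0:
        raise ValueError(f"L must be > 0, got {L}")
    if D_micro < 0:
        raise ValueError(f"D_micro must be >= 0, got {D_micro}")
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    pos = t > 0
    if D_micro > 0 and np.any(pos):
        tmin = t[pos].min()
        q = (math.pi / L) ** 2 * D_micro * tmin
        # k-th term ~ k⁻⁴ exp(−k² q); keep odd k until both damping factors
        # push the tail below rtol relative to the leading term.
        kmax = max(5, int(math.ceil(math.sqrt(math.log(1.0 / rtol) / max(q, 1e-300)))))
        kmax = min(kmax, 20001)
        k = np.arange(1, kmax + 1, 2, dtype=float)
        coef = (16.0 * L * L / math.pi**4) / k**4
        decay = np.exp(-np.outer(t[pos], (k * math.pi / L) ** 2 * D_micro))
        out[pos] = L * L / 6.0 - decay @ coef
    return out[0] if scalar else out


def _hop_msd_laplace(s: np.ndarray, L: float, D: float, kappa: float) -> np.ndarray:
    """Laplace transform of the 1D periodic-semipermeable-barrier MSD.

    Derived by summing the barrier fluxes of the point-source Green's
    function: within each cell the solution is a cosh/sinh combination, the
    semipermeable-barrier jump conditions give a transfer matrix with unit
    determinant whose decaying eigenvalue ``mu`` plays the role of a lattice
    impedance, and the uniform average over the starting position is
    elementary.  All hyperbolics are scaled by exp(-qL) so the expression is
    overflow-free for any (complex) Laplace variable with Re sqrt(s/D) >= 0.
    """
    q = np.sqrt(s / D)
    beta = D * q / kappa
    e2 = np.exp(-2.0 * q * L)
    eqL = np.exp(-q * L)
    ch = 0.5 * (1.0 + e2)            # cosh(qL) e^{-qL}
    sh = 0.5 * (1.0 - e2)            # sinh(qL) e^{-qL}
    lam = 2.0 * ch + beta * sh       # Lambda e^{-qL}
    disc = np.sqrt(1.0 - 4.0 * eqL**2 / lam**2)
    mu = 2.0 * eqL / (lam * (1.0 + disc))
    W = ((ch - mu * eqL) / sh + beta) / q
    G = q * ((W**2 * q**2 + 1.0) * sh + 2.0 * W * q * ch)
    J0 = W * sh + (ch - eqL) / q
    J1 = W * L * sh - W * (ch - eqL) / q + L * ch / q - sh / q**2
    om = 1.0 - mu
    sigma = (q / (L * D * G)) * (
        -L * J0 * (1.0 + mu) / om**2 + (2.0 * J1 - L * J0) / om
    )
    return 2.0 * D / s**2 + (2.0 * D**2 / (kappa * s)) * sigma


_TALBOT_M = 24


def _talbot_invert(fhat, t: np.ndarray, M: int = _TALBOT_M) -> np.ndarray:
    """Fixed-Talbot numerical Laplace inversion, vectorized over t > 0."""
    r = 2.0 * M / (5.0 * t)
    theta = np.arange(1, M) * np.pi / M
    cot = 1.0 / np.tan(theta)
    s = r[:, None] * theta * (cot + 1j)
    sig = theta + (theta * cot - 1.0) * cot
    terms = (np.exp(s * t[:, None]) * fhat(s) * (1.0 + 1j * sig)).real.sum(axis=1)
    head = 0.5 * np.exp(r * t) * fhat(r.astype(complex)).real
    return (r / M) * (head + terms)


def hop_msd_model(t, L: float, D_micro: float, D_MACRO: float) -> np.ndarray:
    """Exact 1D hop-diffusion MSD (see module docstring).

    Requires ``0 <= D_MACRO <= D_micro``; at the upper end the model is free
    diffusion, at the lower end fully confined.
    """
    if D_micro <= 0:
        raise ValueError(f"D_micro must be > 0, got {D_micro}")
    if L <= 0:
        raise ValueError(f"L must be > 0, got {L}")
    if D_MACRO < 0 or D_MACRO > D_micro * (1.0 + 1e-9):
        raise ValueError(
            f"D_MACRO must lie in [0, D_micro={D_micro}], got {D_MACRO}"
        )
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t).astype(float)
    f = min(D_MACRO / D_micro, 1.0)
    if f >= 1.0 - 1e-9:
        out = 2.0 * D_micro * t
    elif f <= 1e-9:
        out = confined_msd_model(t, L, D_micro)
    else:
        kappa = D_micro * D_MACRO / (L * (D_micro - D_MACRO))
        out = np.zeros_like(t)
        pos = t > 0
        out[pos] = _talbot_invert(
            lambda s: _hop_msd_laplace(s, L, D_micro, kappa), t[pos]
        )
    return out[0] if scalar else out


def residency_time(compartment_size: float, D_MACRO: float) -> float:
    """Mean compartment dwell time, s: (compartment size)² / (4 · D_MACRO).

    ``compartment_size`` in µm, ``D_MACRO`` in µm²/s.
    """
    if compartment_size <= 0:
        raise ValueError(f"compartment_size must be > 0, got {compartment_size}")
    if D_MACRO <= 0:
        raise ValueError(f"D_MACRO must be > 0, got {D_MACRO}")
    return compartment_size**2 / (4.0 * D_MACRO)


@dataclass
class AxisFit:
    """Hop-model fit of one coordinate's MSD curve."""

    L: float
    D_micro: float
    D_MACRO: float
    rss: float
    converged: bool
    reason: str = ""


@dataclass
class HopFitResult:
    """Combined per-track hop-diffusion fit.

    Lengths in µm, diffusion coefficients in µm²/s, residency time in s.
    ``compartment_size`` is the geometric mean √(L_x · L_y); ``D_MACRO`` and
    ``D_micro`` are the means of the per-axis values (per-axis slopes summed
    and expressed as a 2D coefficient).  ``residency_time`` is
    compartment_size²/(4 · D_MACRO).  Non-converged tracks carry NaNs and a
    reason, and are excluded from size distributions downstream.
    """

    track_id: str
    L_x: float
    L_y: float
    compartment_size: float
    D_micro: float
    D_MACRO: float
    residency_time: float
    rss: float
    converged: bool
    fit_lags: int
    reason: str = ""
    axis_x: Optional[AxisFit] = None
    axis_y: Optional[AxisFit] = None


def _fit_axis(curve: MSDCurve, fit_lags: int, loc_sigma_floor: float = 0.005) -> AxisFit:
    if curve.axis == "xy":
        raise ValueError("fit_hop expects per-axis MSD curves (axis 'x' or 'y')")
    if not curve.noise_estimated:
        curve = estimate_noise_floor(curve)
    m = min(fit_lags, len(curve))
    t = curve.lag_time[:m]
    y = curve.msd[:m]
    # leading-order SD of the time-averaged MSD at lag n scales as
    # sqrt(n / n_pairs); without the n factor the long, linear part of the
    # curve dominates the fit and washes out the confinement transient
    sigma = np.sqrt(np.arange(1, m + 1) / curve.n_pairs[:m].astype(float))

    # Initialization: the larger of D_2-4 and the lag-1 secant for the
    # microscopic coefficient (D_2-4 underestimates it badly when the
    # compartment equilibrates within a few frames), the long-lag slope for
    # the macroscopic one, the long-lag intercept for the transient
    # amplitude (→ L).
    d24 = estimate_D24(curve)
    d_lag1 = y[0] / (2.0 * t[0])
    D0 = max(d24, d_lag1)
    if D0 <= 0:
        return AxisFit(math.nan, math.nan, math.nan, math.nan, False,
                       "non-positive short-lag diffusion estimate")
    tail = slice(m // 2, m)
    slope_tail, icpt_tail = np.polyfit(t[tail], y[tail], 1)
    f0 = float(np.clip(slope_tail / 2.0 / D0, 1e-4, 0.95))
    amp0 = max(icpt_tail / max(1.0 - f0, 0.05), 0.05 * np.max(y))
    sigma_loc = math.sqrt(max(curve.noise_floor, 0.0) / 2.0)
    L_lo = max(2.0 * sigma_loc, loc_sigma_floor)
    L_hi = 10.0 * math.sqrt(max(np.max(curve.msd_raw[:m]), L_lo**2))
    L0 = float(np.clip(math.sqrt(6.0 * amp0), L_lo * 1.05, L_hi * 0.95))

    def model(tt, L, Dmu, f):
        return hop_msd_model(tt, L, Dmu, f * Dmu)

    p0 = (L0, D0, f0)
    bounds = ([L_lo, D0 / 20.0, 1e-6], [L_hi, D0 * 20.0, 1.0])
    try:
        popt, _ = curve_fit(
            model, t, y, p0=p0, sigma=sigma, bounds=bounds, maxfev=4000
        )
    except (RuntimeError, ValueError) as exc:
        return AxisFit(math.nan, math.nan, math.nan, math.nan, False, f"fit failed: {exc}")
    L, Dmu, f = popt
    resid = y - model(t, *popt)
    rss = float(np.sum(resid**2))
    if f >= FREE_LIKE_RATIO:
        return AxisFit(float(L), float(Dmu), float(f * Dmu), rss, False,
                       "no resolvable compartment")
    if L <= L_lo * 1.01 or L >= L_hi * 0.99:
        return AxisFit(float(L), float(Dmu), float(f * Dmu), rss, False,
                       "L pinned at fit bound")
    return AxisFit(float(L), float(Dmu), float(f * Dmu), rss, True)


def fit_hop(curve_x: MSDCurve, curve_y: MSDCurve, fit_lags: int = 300) -> HopFitResult:
    """Fit the hop model to one track's per-axis MSD curves.

    Each axis is fitted independently over the first ``fit_lags`` lags
    (shrunk with a warning if the curves are shorter) by weighted nonlinear
    least squares with per-lag weights proportional to the pair counts.
    The per-axis noise floors (2σ² each) are estimated by the same lag-2..4
    intercept method before fitting.
    """
    m = min(fit_lags, len(curve_x), len(curve_y))
    if m < fit_lags:
        import warnings

        warnings.warn(
            f"track {curve_x.track_id!r}: only {m} lags available; "
            f"fit range shrunk from {fit_lags}",
            stacklevel=2,
        )
    ax = _fit_axis(curve_x, m)
    ay = _fit_axis(curve_y, m)
    converged = ax.converged and ay.converged
    if converged:
        size = math.sqrt(ax.L * ay.L)
        d_macro = 0.5 * (ax.D_MACRO + ay.D_MACRO)
        d_micro = 0.5 * (ax.D_micro + ay.D_micro)
        tau = residency_time(size, d_macro) if d_macro > 0 else math.nan
        reason = ""
    else:
        size = d_macro = d_micro = tau = math.nan
        reason = "; ".join(
            f"{lbl}: {a.reason}" for lbl, a in (("x", ax), ("y", ay)) if not a.converged
        )
    rss = (ax.rss if math.isfinite(ax.rss) else 0.0) + (
        ay.rss if math.isfinite(ay.rss) else 0.0
    )
    return HopFitResult(
        track_id=curve_x.track_id,
        L_x=ax.L, L_y=ay.L, compartment_size=size,
        D_micro=d_micro, D_MACRO=d_macro, residency_time=tau,
        rss=rss, converged=converged, fit_lags=m, reason=reason,
        axis_x=ax, axis_y=ay,
    )
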
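"""Orchestration: simulate → MSD → classify → fit → detect → report.

Units are seconds and µm throughout the computation; nm and ms appear only
in reports, and floating outputs are printed with 6 significant digits.
Mann–Whitney comparisons are reported per comparison without multiplicity
adjustment.
"""
from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import RNG_ALGORITHM, SimulationConfig, Trajectory, simulate_ensemble
from .msd import compute_msd, estimate_noise_floor
from .classify import ModeResult, build_rd_null, classify_tracks, fraction_simple
from .hopfit import HopFitResult, fit_hop
from .confinement import confinement_index, detect_confinement_segments
from .io import read_trajectories, write_trajectories

__all__ = [
    "ConditionGroup",
    "PipelineConfigError",
    "summarize_group",
    "compare_groups",
    "run_pipeline",
    "RESOLUTION_PRESETS",
]

#: Classification scales for the three acquisition regimes: ultrafast
#: gold-probe tracking (20 µs), fast fluorescence (0.5 ms, time scale 20 ms)
#: and conventional video rate (33 ms, time scale ~1 s).
RESOLUTION_PRESETS = {
    "20us": {"delta_t": 2e-5, "N": 300, "n": 75},
    "0.5ms": {"delta_t": 5e-4, "N": 160, "n": 40},
    "33ms": {"delta_t": 0.033, "N": 60, "n": 30},
}


class PipelineConfigError(ValueError):
    """Unknown or inconsistent pipeline configuration."""


@dataclass
class ConditionGroup:
    """One experimental condition: classified tracks plus optional hop fits."""

    label: str
    results: list[ModeResult]
    hop_fits: Optional[list[HopFitResult]] = None
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def mobile_d24(self) -> np.ndarray:
        return np.array([r.D24 for r in self.results if r.mode != "immobile"])


def summarize_group(group: ConditionGroup) -> dict:
    """Median and mean ± SE of D_2-4 over mobile tracks, simple fraction, counts.

    Hop-fit summaries (median compartment size, D_MACRO and residency time of
    converged fits) are included when available.
    """
    if not group.results:
        raise ValueError(f"group {group.label!r} is empty")
    d = group.mobile_d24()
    out = {
        "label": group.label,
        "n_tracks": len(group.results) + len(group.skipped),
        "n_classified": len(group.results),
        "n_mobile": int(d.size),
        "fraction_simple": fraction_simple(group.results),
    }
    if d.size:
        out["D24_median_um2_s"] = float(np.median(d))
        out["D24_mean_um2_s"] = float(np.mean(d))
        out["D24_se_um2_s"] = float(np.std(d, ddof=1) / math.sqrt(d.size)) if d.size > 1 else 0.0
    else:
        out["D24_median_um2_s"] = out["D24_mean_um2_s"] = out["D24_se_um2_s"] = float("nan")
    if group.hop_fits is not None:
        ok = [f for f in group.hop_fits if f.converged]
        out["n_hop_fits"] = len(group.hop_fits)
        out["n_hop_converged"] = len(ok)
        if ok:
            sizes = np.array([f.compartment_size for f in ok])
            dmac = np.array([f.D_MACRO for f in ok])
            out["compartment_size_median_nm"] = float(np.median(sizes) * 1e3)
            out["Dmacro_median_um2_s"] = float(np.median(dmac))
            out["residency_median_ms"] = float(
                np.median([f.residency_time for f in ok]) * 1e3
            )
    return out


def compare_groups(a: ConditionGroup, b: ConditionGroup) -> float:
    """Two-sided Mann–Whitney U p-value on mobile-track D_2-4 (tie-corrected)."""
    da, db = a.mobile_d24(), b.mobile_d24()
    if da.size == 0 or db.size == 0:
        raise ValueError("both groups need at least one mobile track")
    return float(stats.mannwhitneyu(da, db, alternative="two-sided").pvalue)


_TOP_KEYS = {"groups", "inputs", "analysis", "hop_fit", "confinement", "comparisons"}
_ANALYSIS_KEYS = {"N", "n", "delta_t", "null_sims", "immobile_k"}
_HOPFIT_KEYS = {"enabled", "fit_lags"}
_CONf_KEYS = {"enabled", "window", "threshold", "min_duration_s", "d_ref", "loc_sigma"}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise PipelineConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def _fmt(x) -> object:
    if isinstance(x, float) and math.isfinite(x):
        return float(f"{x:.6g}")
    return x


def run_pipeline(config: dict, out_dir: str | Path, seed: int = 0) -> dict:
    """Execute all configured stages and write the report bundle.

    ``config`` maps group labels either to simulation configs (``groups``)
    or to trajectory CSV paths (``inputs``); the ``analysis`` section fixes
    the classification scale (N, n, δt) and null size.  Outputs: per-group
    stage CSVs, null thresholds JSON, ``summary.json`` and ``run.log`` in
    ``out_dir``.  The bundle is a pure function of (inputs, config, seed).
    """
    _check_keys(config, _TOP_KEYS, "top level")
    analysis = dict(config.get("analysis", {}))
    _check_keys(analysis, _ANALYSIS_KEYS, "analysis")
    hop_cfg = dict(config.get("hop_fit", {}))
    _check_keys(hop_cfg, _HOPFIT_KEYS, "hop_fit")
    conf_cfg = dict(config.get("confinement", {}))
    _check_keys(conf_cfg, _CONf_KEYS, "confinement")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log_lines = [f"hoptrack pipeline; seed={seed}; rng={RNG_ALGORITHM}"]
    for mod in ("numpy", "scipy", "pandas"):
        log_lines.append(f"{mod}=={__import__(mod).__version__}")

    # --- stage 1: obtain trajectories per group -------------------------
    ensembles: dict[str, list[Trajectory]] = {}
    for i, (label, sim) in enumerate(sorted(config.get("groups", {}).items())):
        cfg = SimulationConfig.from_dict(
            {**sim, "seed": int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31)}
        )
        trajs = simulate_ensemble(cfg)
        ensembles[label] = trajs
        write_trajectories(trajs, out_dir / f"trajectories_{label}.csv")
        log_lines.append(f"group {label}: simulated {len(trajs)} tracks ({cfg.mode})")
    for label, path in sorted(config.get("inputs", {}).items()):
        if label in ensembles:
            raise PipelineConfigError(f"group {label!r} defined in both groups and inputs")
        ensembles[label] = read_trajectories(path)
        log_lines.append(f"group {label}: read {len(ensembles[label])} tracks from {path}")
    if not ensembles:
        raise PipelineConfigError("no groups or inputs configured")

    # --- stage 2: null calibration --------------------------------------
    N = int(analysis.get("N", 160))
    n = int(analysis.get("n", 40))
    delta_t = float(analysis.get("delta_t", next(iter(ensembles.values()))[0].delta_t))
    null_sims = int(analysis.get("null_sims", 10_000))
    k_imm = float(analysis.get("immobile_k", 2.0))
    null_seed = int(np.random.SeedSequence([seed, 9_999]).generate_state(1)[0] % 2**31)
    null = build_rd_null(N, n, delta_t, n_sims=null_sims, seed=null_seed)
    null.to_json(out_dir / "rd_null.json")
    log_lines.append(
        f"RD null: N={N} n={n} delta_t={delta_t} n_sims={null_sims} "
        f"rd_min={null.rd_min:.6g} rd_max={null.rd_max:.6g}"
    )

    # --- stage 3: per-group MSD, classification, optional fits ----------
    groups: dict[str, ConditionGroup] = {}
    for label, trajs in ensembles.items():
        msd_rows = []
        for tr in trajs:
            curve = estimate_noise_floor(compute_msd(tr, max_lag=min(n, len(tr) - 1)))
            for k in range(len(curve)):
                msd_rows.append(
                    (tr.track_id, k + 1, curve.lag_time[k], curve.msd[k],
                     curve.n_pairs[k], curve.noise_floor)
                )
        pd.DataFrame(
            msd_rows,
            columns=["track_id", "lag_n", "delta_t_s", "msd_um2", "n_pairs", "noise_floor_um2"],
        ).to_csv(out_dir / f"msd_{label}.csv", index=False, float_format="%.6g")

        results, skipped = classify_tracks(trajs, null, k_immobile=k_imm)
        pd.DataFrame(
            [(r.track_id, r.mode, r.rd, r.D24, r.N, r.n, r.delta_t) for r in results],
            columns=["track_id", "mode", "rd", "D24_um2_s", "N", "n", "delta_t_s"],
        ).to_csv(out_dir / f"classification_{label}.csv", index=False, float_format="%.6g")
        for tid, reason in skipped:
            log_lines.append(f"group {label}: skipped {tid}: {reason}")

        hop_fits = None
        if hop_cfg.get("enabled", False):
            fit_lags = int(hop_cfg.get("fit_lags", 300))
            hop_fits = []
            for tr in trajs:
                ml = min(fit_lags, len(tr) - 1)
                cx = compute_msd(tr, max_lag=ml, axis="x")
                cy = compute_msd(tr, max_lag=ml, axis="y")
                hop_fits.append(fit_hop(cx, cy, fit_lags=fit_lags))
            pd.DataFrame(
                [
                    (f.track_id, f.L_x * 1e3, f.L_y * 1e3, f.compartment_size * 1e3,
                     f.D_micro, f.D_MACRO, f.residency_time * 1e3, f.converged, f.rss)
                    for f in hop_fits
                ],
                columns=["track_id", "Lx_nm", "Ly_nm", "size_nm", "Dmicro_um2_s",
                         "Dmacro_um2_s", "residency_ms", "converged", "rss"],
            ).to_csv(out_dir / f"hopfit_{label}.csv", index=False, float_format="%.6g")

        if conf_cfg.get("enabled", False):
            seg_rows = []
            for tr in trajs:
                prof = confinement_index(
                    tr,
                    window=int(conf_cfg.get("window", 16)),
                    D_ref=conf_cfg.get("d_ref"),
                    loc_sigma=float(conf_cfg.get("loc_sigma", 0.02)),
                )
                for s in detect_confinement_segments(
                    prof,
                    threshold=float(conf_cfg.get("threshold", 2.0)),
                    min_duration=float(conf_cfg.get("min_duration_s", 0.004)),
                ):
                    seg_rows.append(
                        (tr.track_id, s.start_frame, s.end_frame,
                         s.duration * 1e3, s.max_index)
                    )
            pd.DataFrame(
                seg_rows,
                columns=["track_id", "start_frame", "end_frame", "duration_ms", "max_index"],
            ).to_csv(out_dir / f"confinement_{label}.csv", index=False, float_format="%.6g")

        groups[label] = ConditionGroup(label, results, hop_fits, skipped)

    # --- stage 4: report -------------------------------------------------
    summary: dict = {
        "seed": seed,
        "analysis": {"N": N, "n": n, "delta_t_s": delta_t, "null_sims": null_sims,
                     "immobile_k": k_imm,
                     "rd_min": _fmt(null.rd_min), "rd_max": _fmt(null.rd_max)},
        "groups": {},
        "comparisons": {},
    }
    for label, grp in groups.items():
        summary["groups"][label] = {k: _fmt(v) for k, v in summarize_group(grp).items()}
    for pair in config.get("comparisons", []):
        a, b = pair
        if a not in groups or b not in groups:
            raise PipelineConfigError(f"comparison {pair} references unknown group")
        summary["comparisons"][f"{a}_vs_{b}"] = _fmt(compare_groups(groups[a], groups[b]))
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, allow_nan=True))
    log_lines.append(f"done in {time.time() - t0:.1f} s")
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return {"summary": summary, "groups": groups, "null": null, "out_dir": str(out_dir)}
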
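"""Reading and writing the package's plain-text formats.

Trajectory CSV dialect: header ``track_id,frame,t_s,x_um,y_um``, frames
0-based and consecutive within a track, uniform frame interval, no gaps.
Simulated ensembles are accompanied by a ``<name>.meta.json`` sidecar echoing
the generating configuration and RNG scheme.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .simulate import SimulationConfig, Trajectory

__all__ = [
    "TRAJ_COLUMNS",
    "TrajectoryFormatError",
    "read_trajectories",
    "write_trajectories",
    "load_config",
]

TRAJ_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]


class TrajectoryFormatError(ValueError):
    """Malformed trajectory CSV (missing columns, gaps, duplicates...)."""


def write_trajectories(
    trajs: Sequence[Trajectory],
    path: str | Path,
    sidecar: bool = True,
) -> None:
    """Write an ensemble to CSV (one file), with an optional metadata sidecar."""
    path = Path(path)
    frames = []
    for tr in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "track_id": tr.track_id,
                    "frame": np.arange(len(tr)),
                    "t_s": tr.t,
                    "x_um": tr.x,
                    "y_um": tr.y,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.9g")
    if sidecar:
        meta: dict = {"n_traj": len(trajs)}
        truths = {id(tr.truth): tr.truth for tr in trajs if tr.truth is not None}
        if truths:
            # one config per ensemble in normal use
            meta["config"] = next(iter(truths.values())).to_dict()
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2)
        )


def read_trajectories(path: str | Path) -> list[Trajectory]:
    """Parse and validate a trajectory CSV.

    Malformed rows are rejected with errors naming the offending track and
    CSV line number (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(f"{path}: missing columns {missing}")
    df["_line"] = np.arange(2, len(df) + 2)  # header is line 1
    trajs: list[Trajectory] = []
    for track_id, g in df.groupby("track_id", sort=False):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy()
        dup = g[g["frame"].duplicated()]
        if len(dup):
            line = int(dup["_line"].iloc[0])
            raise TrajectoryFormatError(
                f"{path}: duplicate (track, frame) = ({track_id!r}, "
                f"{int(dup['frame'].iloc[0])}) at line {line}"
            )
        expected = np.arange(frames[0], frames[0] + len(frames))
        if not np.array_equal(frames, expected):
            bad = int(np.flatnonzero(frames != expected)[0])
            line = int(g["_line"].iloc[bad])
            raise TrajectoryFormatError(
                f"{path}: gap in frames for track {track_id!r} "
                f"near frame {int(frames[bad])} (line {line})"
            )
        t = g["t_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise TrajectoryFormatError(
                f"{path}: track {track_id!r} has fewer than 2 frames"
            )
        dts = np.diff(t)
        if np.any(dts <= 0):
            bad = int(np.flatnonzero(dts <= 0)[0]) + 1
            line = int(g["_line"].iloc[bad])
            raise TrajectoryFormatError(
                f"{path}: non-monotone time for track {track_id!r} at line {line}"
            )
        delta_t = float(np.median(dts))
        if not np.allclose(dts, delta_t, rtol=1e-6, atol=1e-12):
            bad = int(np.argmax(np.abs(dts - delta_t))) + 1
            line = int(g["_line"].iloc[bad])
            raise TrajectoryFormatError(
                f"{path}: non-uniform frame interval for track {track_id!r} at line {line}"
            )
        trajs.append(
            Trajectory(
                str(track_id), delta_t, t,
                g["x_um"].to_numpy(dtype=float), g["y_um"].to_numpy(dtype=float),
            )
        )
    if not trajs:
        raise TrajectoryFormatError(f"{path}: no tracks found")
    return trajs


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file as a dict."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
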
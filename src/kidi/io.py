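"""CSV / config readers and writers plus summary helpers.

Trajectory CSV dialect: columns ``time_h, x1_od, x2_od, glucose_g_per_L,
trp_mg_per_L, tyr_mg_per_L``, header mandatory, UTF-8, '.' decimal
separator.  Extra columns are tolerated (preserved in metadata); missing
required columns, non-monotone time or negative values are parse errors
that name the offending row/column.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import Trajectory, TRAJECTORY_COLUMNS
from .interactions import InteractionProfile

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"


class TrajectoryParseError(ValueError):
    pass


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    traj.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"{path}: missing columns {missing}")
    extras = [c for c in df.columns if c not in TRAJECTORY_COLUMNS]
    if extras:
        log.warning("%s: ignoring extra columns %s", path, extras)

    times = df["time_h"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(times) <= 0)
    if bad.size:
        raise TrajectoryParseError(
            f"{path}: time_h not strictly increasing at row {bad[0] + 1}"
        )
    states = df[list(TRAJECTORY_COLUMNS[1:])].to_numpy(dtype=float)
    if np.any(states < 0) or np.any(times < 0):
        r, c = np.argwhere(states < 0)[0] if np.any(states < 0) else (0, 0)
        col = TRAJECTORY_COLUMNS[1:][c] if np.any(states < 0) else "time_h"
        raise TrajectoryParseError(f"{path}: negative value in column {col}, row {r}")
    meta = {"source": str(path)}
    if extras:
        meta["extra_columns"] = {c: df[c].tolist() for c in extras}
    return Trajectory(times=times, states=states, metadata=meta)


def write_interactions(profile: InteractionProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def default_config_path() -> Path:
    """Path of the bundled default parameter/scenario config."""
    return Path(__file__).parent / "configs" / "default.yaml"


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config file (YAML is a JSON superset here)."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def dump_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def sign_change_times(
    times: np.ndarray, values: np.ndarray, deadband: float = 1e-3
) -> list[float]:
    """Zero-crossing times of a series, ignoring |value| < deadband chatter.

    Values inside the deadband are treated as sign-less; a crossing is
    recorded when the sign flips between consecutive signed samples, with
    the crossing time linearly interpolated.
    """
    signed = np.where(np.abs(values) >= deadband, np.sign(values), 0.0)
    crossings = []
    last_sign = 0.0
    last_idx = None
    for k, s in enumerate(signed):
        if s == 0.0:
            continue
        if last_sign != 0.0 and s != last_sign:
            i0 = last_idx
            # interpolate on the raw series between the two signed samples
            v0, v1 = values[i0], values[k]
            t0, t1 = times[i0], times[k]
            tc = t0 + (t1 - t0) * (0.0 - v0) / (v1 - v0) if v1 != v0 else t0
            crossings.append(float(tc))
        last_sign = s
        last_idx = k
    return crossings


def sign_sequence(values: np.ndarray, deadband: float = 1e-3) -> list[int]:
    """Collapsed sequence of signs (+1/-1) taken by a series."""
    signed = np.where(np.abs(values) >= deadband, np.sign(values), 0.0)
    seq: list[int] = []
    for s in signed:
        if s != 0.0 and (not seq or seq[-1] != int(s)):
            seq.append(int(s))
    return seq


def profile_summary(profile: InteractionProfile, deadband: float = 1e-3) -> dict:
    """Min/max of each coefficient and gamma sign-change times."""
    t = np.asarray(profile.times, dtype=float)
    out: dict = {"n_points": len(profile)}
    for attr in ("a_plus_12", "a_minus_12", "a_12", "a_plus_21", "a_minus_21",
                 "a_21", "a_11", "a_22"):
        series = profile.series(attr)
        out[attr] = {"min": float(series.min()), "max": float(series.max())}
    for pair in ("12", "21"):
        g = profile.series(f"gamma_{pair}")
        defined = profile.series(f"defined_{pair}").astype(bool)
        gd = g[defined]
        out[f"gamma_{pair}"] = {
            "min": float(gd.min()) if gd.size else None,
            "max": float(gd.max()) if gd.size else None,
            "sign_changes_h": sign_change_times(t[defined], gd, deadband),
            "sign_sequence": sign_sequence(gd, deadband),
        }
    return out
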
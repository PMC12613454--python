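"""Per-wall outcome metrics and their transforms.

Two outcomes are analyzed per wall crossing: the absolute lateral miss
|Error| (m) at the time of pendulum-wall contact, and the interaction force
|IntForce| (N), the mean magnitude of the human-robot force over the window
between consecutive inter-wall midpoints.  Both are log10-transformed before
model fitting to correct their skew; exact zeros are floored at a documented
epsilon first.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .pendulum import PendulumParams
from .protocol import WallSchedule, set_score

logger = logging.getLogger(__name__)

__all__ = [
    "per_wall_error",
    "per_wall_interaction_force",
    "log10_transform",
    "LOG_FLOOR",
]

#: floor applied to |Error| (m) and |IntForce| (N) before log10
LOG_FLOOR = 1e-4


def per_wall_error(
    t: np.ndarray,
    mass_y: np.ndarray,
    schedule: WallSchedule,
) -> np.ndarray:
    """Absolute miss |mass_y - b| at each wall-crossing time.

    The trajectory must span every crossing; a crossing that falls between
    samples is linearly interpolated (with a logged warning).
    """
    t = np.asarray(t, dtype=float)
    mass_y = np.asarray(mass_y, dtype=float)
    times = schedule.crossing_times
    if times[-1] > t[-1] + 1e-9 or times[0] < t[0] - 1e-9:
        raise ValueError("trajectory does not span all crossing times")
    out = np.empty(len(times))
    for k, (tc, tgt) in enumerate(zip(times, schedule.targets)):
        idx = np.searchsorted(t, tc)
        if idx < len(t) and abs(t[idx] - tc) < 1e-9:
            y = mass_y[idx]
        else:
            logger.warning("no sample at crossing t=%.4f; interpolating", tc)
            y = float(np.interp(tc, t, mass_y))
        out[k] = abs(y - tgt.offset_b)
    return out


def per_wall_interaction_force(
    t: np.ndarray,
    force: np.ndarray,
    schedule: WallSchedule,
) -> np.ndarray:
    """Mean |force| per wall over consecutive inter-wall midpoint windows.

    For wall k crossed at ``t_k`` with inter-wall interval ``I``, the window
    is ``[t_k - I/2, t_k + I/2]``, clipped to the recorded span at the set
    boundaries (first/last wall).
    """
    t = np.asarray(t, dtype=float)
    force = np.asarray(force, dtype=float)
    times = schedule.crossing_times
    if len(times) > 1:
        half = 0.5 * float(np.min(np.diff(times)))
    else:
        half = 0.5 * times[0]
    out = np.empty(len(times))
    for k, tc in enumerate(times):
        lo = max(tc - half, t[0])
        hi = min(tc + half, t[-1])
        mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
        if not np.any(mask):
            raise ValueError(f"empty force window for wall {k}")
        # trapezoidal time average is robust to non-uniform sampling
        tm, fm = t[mask], np.abs(force[mask])
        if len(tm) == 1:
            out[k] = fm[0]
        else:
            out[k] = np.trapezoid(fm, tm) / (tm[-1] - tm[0])
    return out


def log10_transform(
    records: pd.DataFrame,
    columns: tuple[str, ...] = ("abs_error", "int_force"),
    floor: float = LOG_FLOOR,
) -> pd.DataFrame:
    """Add log10 columns, flooring values below ``floor`` first.

    ``abs_error`` becomes ``log10_abs_error`` and so on.  The input frame is
    not modified.
    """
    out = records.copy()
    for col in columns:
        vals = np.asarray(out[col], dtype=float)
        out[f"log10_{col}"] = np.log10(np.maximum(vals, floor))
    return out


def set_scores(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-set mean scores (equals the mean of the per-wall scores exactly)."""
    keys = ["ID", "Group", "Stage", "Task", "sIndex"]
    agg = trials.groupby(keys, sort=False)["score"].agg(list).reset_index()
    agg["set_score"] = agg["score"].map(set_score)
    return agg.drop(columns="score")
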
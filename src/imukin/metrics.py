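"""Evaluation of estimated kinematics against a reference record.

Provides the comparisons used to validate wearable kinematics against a
reference (e.g. optical motion capture, or the simulator's ground truth):
per-coordinate root-mean-square error and Pearson correlation, error growth
over time (drift), gait-cycle averaging to a 0-100% normalized cycle, and the
foot progression angle from virtual heel/toe markers.

The reference is always resampled (linear interpolation) onto the estimate's
timestamps, never the other way round, so that an online run's decimated
clock does not fabricate estimate samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .ik import MotionRecord
from .skeleton import Pose, SkeletonModel, forward_kinematics

__all__ = [
    "ComparisonReport",
    "resample_to",
    "rmse",
    "pearson",
    "drift_curve",
    "cycle_average",
    "foot_progression_angle",
    "compare",
    "DEFAULT_HEEL_OFFSET",
    "DEFAULT_TOE_OFFSET",
]

#: Virtual heel marker in the foot frame (m): just behind the ankle.
DEFAULT_HEEL_OFFSET = np.array([-0.05, -0.04, 0.0])
#: Virtual second-metatarsal-head marker in the foot frame (m).
DEFAULT_TOE_OFFSET = np.array([0.15, -0.04, 0.0])


def _common_columns(est: MotionRecord, ref: MotionRecord) -> tuple[str, ...]:
    cols = tuple(n for n in est.names if n in ref.names)
    if not cols:
        raise ValueError("records share no coordinates")
    return cols


def resample_to(ref: MotionRecord, times: np.ndarray) -> MotionRecord:
    """Linear-interpolate a record onto new timestamps (must be covered)."""
    if times[0] < ref.time[0] - 1e-9 or times[-1] > ref.time[-1] + 1e-9:
        raise ValueError("estimate time range not covered by reference")
    data = np.column_stack([np.interp(times, ref.time, ref.data[:, j])
                            for j in range(ref.data.shape[1])])
    rate = 1.0 / float(np.median(np.diff(times))) if len(times) > 1 else ref.rate
    return MotionRecord(time=times, data=data, names=ref.names, rate=rate)


def rmse(est: MotionRecord, ref: MotionRecord) -> dict[str, float]:
    """Per-coordinate root-mean-square error in degrees.

    The reference is resampled to the estimate's timestamps first.
    """
    cols = _common_columns(est, ref)
    ref_rs = resample_to(ref, est.time)
    return {c: float(np.sqrt(np.mean((est.column(c) - ref_rs.column(c)) ** 2)))
            for c in cols}


def overall_rmse(est: MotionRecord, ref: MotionRecord) -> float:
    """Mean of the per-coordinate RMSEs."""
    values = rmse(est, ref)
    return float(np.mean(list(values.values())))


def pearson(est: MotionRecord, ref: MotionRecord) -> dict[str, float]:
    """Per-coordinate Pearson correlation; NaN flags zero variance."""
    cols = _common_columns(est, ref)
    ref_rs = resample_to(ref, est.time)
    out = {}
    for c in cols:
        a, b = est.column(c), ref_rs.column(c)
        if len(a) < 2 or np.std(a) == 0.0 or np.std(b) == 0.0:
            out[c] = float("nan")
        else:
            out[c] = float(stats.pearsonr(a, b).statistic)
    return out


def drift_curve(est: MotionRecord, ref: MotionRecord, window: float = 10.0,
                hop: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """RMSE (averaged across coordinates) in sliding time windows.

    Returns ``(window_centers, rmse_values)``.  Exposes the growth of error
    with time caused by integrated gyro bias and the unobservable heading.
    """
    duration = float(est.time[-1] - est.time[0])
    if window > duration + 1e-9:
        raise ValueError("window longer than the record")
    hop = window / 2.0 if hop is None else hop
    cols = _common_columns(est, ref)
    ref_rs = resample_to(ref, est.time)
    err = np.column_stack([est.column(c) - ref_rs.column(c) for c in cols])
    centers, values = [], []
    start = float(est.time[0])
    while start + window <= est.time[-1] + 1e-9:
        m = (est.time >= start - 1e-12) & (est.time <= start + window + 1e-12)
        per_coord = np.sqrt(np.mean(err[m] ** 2, axis=0))
        centers.append(start + window / 2.0)
        values.append(float(per_coord.mean()))
        start += hop
    return np.asarray(centers), np.asarray(values)


def cycle_average(record: MotionRecord, events: Sequence[float],
                  n_points: int = 101
                  ) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Average cycles between consecutive events onto a 0-100% base.

    Returns ``(percent, mean_curves, std_curves)`` keyed by coordinate.
    Requires at least two events, all inside the record's time range.
    """
    events = sorted(float(e) for e in events)
    if len(events) < 2:
        raise ValueError("need at least 2 cycle events")
    if events[0] < record.time[0] - 1e-9 or events[-1] > record.time[-1] + 1e-9:
        raise ValueError("cycle events outside the record")
    percent = np.linspace(0.0, 100.0, n_points)
    curves: dict[str, list[np.ndarray]] = {n: [] for n in record.names}
    for t0, t1 in zip(events[:-1], events[1:]):
        ts = np.linspace(t0, t1, n_points)
        for j, n in enumerate(record.names):
            curves[n].append(np.interp(ts, record.time, record.data[:, j]))
    mean = {n: np.mean(np.vstack(c), axis=0) for n, c in curves.items()}
    std = {n: np.std(np.vstack(c), axis=0) for n, c in curves.items()}
    return percent, mean, std


def foot_progression_angle(model: SkeletonModel, record: MotionRecord,
                           heel_offset=DEFAULT_HEEL_OFFSET,
                           toe_offset=DEFAULT_TOE_OFFSET,
                           step_windows: Sequence[tuple[float, float]] = (),
                           foot_segment: str = "calcn_r") -> np.ndarray:
    """Per-step foot progression angle in degrees, toe-out positive.

    Virtual heel and toe (second metatarsal head) markers are placed at fixed
    offsets in the foot frame; the instantaneous angle is the signed angle
    between the horizontal projection of the heel-to-toe vector and the
    direction of progression (world +x), positive toward the lateral (+z)
    side.  Each step's value is the mean over its ``(t_start, t_end)``
    window; with no windows the whole record is one step.
    """
    if foot_segment not in model.segments:
        raise KeyError(f"foot segment {foot_segment!r} not in model")
    heel = np.asarray(heel_offset, dtype=float)
    toe = np.asarray(toe_offset, dtype=float)
    fpa = np.empty(len(record))
    for i in range(len(record)):
        fk = forward_kinematics(model, record.pose_at(i))
        q = fk[foot_segment]
        d = q.rotate(toe) - q.rotate(heel)
        fpa[i] = math.degrees(math.atan2(d[2], d[0]))
    if not step_windows:
        return np.array([float(fpa.mean())])
    out = []
    for t0, t1 in step_windows:
        m = (record.time >= t0 - 1e-12) & (record.time <= t1 + 1e-12)
        if not m.any():
            raise ValueError(f"step window ({t0}, {t1}) contains no samples")
        out.append(float(fpa[m].mean()))
    return np.asarray(out)


@dataclass(frozen=True)
class ComparisonReport:
    """Per-coordinate accuracy summary of an estimate against a reference."""

    rmse_deg: Mapping[str, float]
    pearson_r: Mapping[str, float]
    drift_times: np.ndarray
    drift_rmse: np.ndarray

    @property
    def overall_rmse(self) -> float:
        return float(np.mean(list(self.rmse_deg.values())))

    def to_rows(self) -> list[dict]:
        return [{"coordinate": c, "rmse_deg": self.rmse_deg[c],
                 "pearson_r": self.pearson_r[c]} for c in self.rmse_deg]


def compare(est: MotionRecord, ref: MotionRecord,
            drift_window: float = 10.0) -> ComparisonReport:
    """Full accuracy report: RMSE, Pearson r and a drift curve."""
    duration = float(est.time[-1] - est.time[0])
    window = min(drift_window, duration) if duration > 0 else drift_window
    times, values = drift_curve(est, ref, window=window)
    return ComparisonReport(rmse_deg=rmse(est, ref),
                            pearson_r=pearson(est, ref),
                            drift_times=times, drift_rmse=values)
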
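"""Standing-pose system calibration.

Because no magnetometer is used, each sensor's Mahony estimate starts with an
arbitrary heading.  Calibration removes this indeterminacy and binds the
sensors to the skeleton in three steps, all from one stationary standing
recording (subject in the neutral pose, arms at the sides):

1. estimate each sensor's orientation with the Mahony filter
   (:func:`~imukin.fusion.static_orientation`);
2. compute the *target heading* as the circular mean of all sensor headings
   and pre-rotate each orientation about the world vertical so its heading
   equals the target (:func:`align_headings`) -- circular averaging via unit
   vectors is used because an arithmetic mean misbehaves at the +/-180 wrap;
3. register each sensor to its segment: a constant *registration rotation*
   per sensor is chosen so that, at the standing pose, the measured and
   model segment orientations agree exactly.  Mounting misalignments that
   are constant over the session are absorbed into this rotation.

The resulting :class:`CalibrationState` converts any later raw sensor
orientation into a model-segment orientation target for the inverse
kinematics.  Registration rotations are constant for the session; a fresh
calibration replaces them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .fusion import FusionSettings, GyroBias, static_orientation
from .imu_sim import ImuStream
from .rotations import (DegenerateHeadingError, Quaternion, heading_angle,
                        rotate_heading, wrap_angle)
from .skeleton import ROOT_SEGMENT, SkeletonModel, forward_kinematics

__all__ = [
    "CalibrationError",
    "SensorCalibration",
    "CalibrationState",
    "circular_mean_deg",
    "align_headings",
    "calibrate",
]


class CalibrationError(RuntimeError):
    """Calibration could not be completed; the message names the sensor."""


@dataclass(frozen=True)
class SensorCalibration:
    """Per-sensor constants fixed at calibration time."""

    heading_correction: float  # deg, pre-rotation about world vertical
    initial_orientation: Quaternion  # raw Mahony estimate at standing
    registration: Quaternion  # sensor-frame rotation binding sensor to model
    bias: GyroBias


@dataclass(frozen=True)
class CalibrationState:
    """Full system calibration for one sensor set and model."""

    target_heading: float
    sensors: Mapping[str, SensorCalibration]
    calibrated_at: float = 0.0

    def segment_orientation(self, segment: str, raw: Quaternion,
                            model: SkeletonModel) -> Quaternion:
        """Convert a raw sensor orientation into a model segment orientation.

        Applies the heading correction (pre-rotation about vertical), the
        registration rotation, and removes the nominal mounting.
        """
        cal = self.sensors[segment]
        corrected = rotate_heading(raw, cal.heading_correction)
        return corrected * cal.registration * model.mounting[segment].conjugate()


def circular_mean_deg(angles_deg) -> float:
    """Circular mean of angles in degrees, result in (-180, 180]."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    s, c = np.sin(a).mean(), np.cos(a).mean()
    if math.hypot(s, c) < 1e-12:
        raise ValueError("circular mean undefined: headings cancel")
    return wrap_angle(math.degrees(math.atan2(s, c)))


def align_headings(orientations: Mapping[str, Quaternion]
                   ) -> tuple[float, dict[str, float], dict[str, Quaternion]]:
    """Align all sensor headings to their circular mean.

    Returns ``(target_heading, corrections, corrected)`` where
    ``corrections[s]`` is the heading increment applied to sensor ``s`` and
    ``corrected[s]`` the re-headed orientation.  Inclinations are untouched.
    A sensor whose forward axis is vertical makes the heading undefined and
    raises :class:`CalibrationError` naming that sensor.
    """
    if not orientations:
        raise CalibrationError("no sensor orientations to align")
    headings: dict[str, float] = {}
    for sensor, q in orientations.items():
        try:
            headings[sensor] = heading_angle(q)
        except DegenerateHeadingError as exc:
            raise CalibrationError(
                f"sensor {sensor!r}: degenerate heading ({exc})") from exc
    target = circular_mean_deg(list(headings.values()))
    corrections = {s: wrap_angle(target - h) for s, h in headings.items()}
    corrected = {s: rotate_heading(orientations[s], corrections[s])
                 for s in orientations}
    return target, corrections, corrected


def calibrate(model: SkeletonModel,
              static_streams: Mapping[str, ImuStream],
              settings: FusionSettings,
              biases: Mapping[str, GyroBias],
              tracked_segments=None) -> CalibrationState:
    """Calibrate a sensor set against the model's neutral standing pose.

    ``static_streams`` maps segment names to stationary standing recordings;
    one stream per tracked segment including the pelvis is required.  The
    registration rotation of sensor ``s`` is chosen so that the corrected
    orientation composed with it reproduces ``FK_neutral(segment) * mounting``
    exactly, making the standing pose the exact zero of all joint angles.
    """
    tracked = tuple(tracked_segments) if tracked_segments is not None \
        else tuple(static_streams)
    if ROOT_SEGMENT not in tracked:
        raise CalibrationError("pelvis stream is required (base segment)")
    missing = [s for s in tracked if s not in static_streams]
    if missing:
        raise CalibrationError(f"missing static stream for segment(s) {missing}")
    raw: dict[str, Quaternion] = {}
    calibrated_at = 0.0
    for seg in tracked:
        stream = static_streams[seg]
        raw[seg] = static_orientation(stream, settings,
                                      biases.get(seg, GyroBias.zero()))
        calibrated_at = float(stream.t[-1])
    target, corrections, corrected = align_headings(raw)
    neutral_fk = forward_kinematics(model, model.neutral_pose())
    sensors: dict[str, SensorCalibration] = {}
    for seg in tracked:
        expected = neutral_fk[seg] * model.mounting[seg]
        registration = corrected[seg].conjugate() * expected
        sensors[seg] = SensorCalibration(
            heading_correction=corrections[seg],
            initial_orientation=raw[seg],
            registration=registration,
            bias=biases.get(seg, GyroBias.zero()))
    return CalibrationState(target_heading=target, sensors=sensors,
                            calibrated_at=calibrated_at)
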
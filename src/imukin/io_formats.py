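"""Readers and writers for every on-disk artifact.

* per-sensor IMU streams: comma-delimited CSV with columns
  ``time_s, ax, ay, az, gx, gy, gz`` (accelerometer m/s^2, gyroscope deg/s);
* a dataset manifest (YAML) binding sensor files to model segments and,
  for synthetic datasets, pointing at the ground-truth motion file;
* motion records: OpenSim-style ``.sto``/``.mot`` tab-delimited text with a
  header terminated by ``endheader``, ``time`` as the first column, angles
  always in degrees (``inDegrees=yes``);
* gyro-bias and calibration stores: small YAML documents persisted between
  recordings.

All files are UTF-8 with Unix newlines; numbers are written with 9
significant digits, making write/read round trips lossless at that precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationState, SensorCalibration
from .fusion import GyroBias
from .ik import MotionRecord
from .imu_sim import ImuStream
from .rotations import Quaternion

__all__ = [
    "FormatError",
    "read_imu_csv",
    "write_imu_csv",
    "read_sto",
    "write_sto",
    "read_manifest",
    "write_manifest",
    "read_bias_file",
    "write_bias_file",
    "read_calibration",
    "write_calibration",
]

_IMU_COLUMNS = ("time_s", "ax", "ay", "az", "gx", "gy", "gz")
_FMT = "%.9g"


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


# -- IMU CSV ---------------------------------------------------------------

def write_imu_csv(path: str | Path, stream: ImuStream) -> None:
    df = pd.DataFrame(
        np.column_stack([stream.t, stream.accel, stream.gyro]),
        columns=list(_IMU_COLUMNS))
    df.to_csv(path, index=False, float_format=_FMT, lineterminator="\n")


def read_imu_csv(path: str | Path, sensor_id: str | None = None,
                 jitter_tol: float = 0.01) -> ImuStream:
    """Read an IMU stream; column order is free, names are matched.

    Raises :class:`FormatError` for a missing column, a non-numeric cell,
    non-monotone timestamps, or sampling jitter beyond ``jitter_tol``
    (fraction of the nominal interval).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    df = df[list(_IMU_COLUMNS)]
    try:
        arr = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path.name}: non-numeric cell ({exc})") from exc
    if not np.isfinite(arr).all():
        raise FormatError(f"{path.name}: non-finite value")
    t = arr[:, 0]
    if len(t) > 1:
        dt = np.diff(t)
        if (dt <= 0).any():
            raise FormatError(f"{path.name}: timestamps not strictly increasing")
        nominal = np.median(dt)
        if np.abs(dt - nominal).max() > jitter_tol * nominal:
            raise FormatError(
                f"{path.name}: non-uniform sampling beyond {jitter_tol:.0%} jitter")
        rate = 1.0 / nominal
    else:
        rate = 0.0
    return ImuStream(sensor_id or path.stem, rate, t, arr[:, 1:4], arr[:, 4:7])


# -- .sto / .mot motion files ----------------------------------------------

def write_sto(path: str | Path, record: MotionRecord,
              name: str | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{name or path.stem}\n")
        fh.write(f"version=1\nnRows={len(record)}\n"
                 f"nColumns={len(record.names) + 1}\n"
                 "inDegrees=yes\nendheader\n")
        fh.write("time\t" + "\t".join(record.names) + "\n")
        for t, row in zip(record.time, record.data):
            cells = [_FMT % t] + [_FMT % v for v in row]
            fh.write("\t".join(cells) + "\n")


def read_sto(path: str | Path) -> MotionRecord:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    try:
        end = next(i for i, line in enumerate(lines)
                   if line.strip() == "endheader")
    except StopIteration:
        raise FormatError(f"{path.name}: no endheader line") from None
    for line in lines[:end]:
        if "=" in line:
            k, _, v = line.partition("=")
            meta[k.strip()] = v.strip()
    labels = lines[end + 1].split("\t")
    if not labels or labels[0] != "time":
        raise FormatError(f"{path.name}: first column must be 'time'")
    rows = [line.split("\t") for line in lines[end + 2:] if line.strip()]
    if "nRows" in meta and int(meta["nRows"]) != len(rows):
        raise FormatError(
            f"{path.name}: nRows={meta['nRows']} but {len(rows)} data rows")
    if "nColumns" in meta and int(meta["nColumns"]) != len(labels):
        raise FormatError(
            f"{path.name}: nColumns={meta['nColumns']} but {len(labels)} labels")
    try:
        arr = np.array(rows, dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path.name}: non-numeric cell ({exc})") from exc
    if arr.size == 0:
        arr = arr.reshape(0, len(labels))
    t = arr[:, 0]
    rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    return MotionRecord(time=t, data=arr[:, 1:], names=tuple(labels[1:]),
                        rate=rate)


# -- dataset manifest -------------------------------------------------------

def write_manifest(path: str | Path, sensor_files: Mapping[str, str],
                   segment_map: Mapping[str, str],
                   truth_file: str | None = None,
                   model: str | None = None) -> None:
    """Bind per-sensor CSV files to model segments (and optional truth)."""
    doc = {"sensors": {s: {"file": sensor_files[s],
                           "segment": segment_map[s]} for s in sensor_files}}
    if truth_file:
        doc["truth"] = truth_file
    if model:
        doc["model"] = model
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "sensors" not in doc:
        raise FormatError(f"{Path(path).name}: manifest must list sensors")
    return doc


# -- bias store --------------------------------------------------------------

def write_bias_file(path: str | Path, biases: Mapping[str, GyroBias]) -> None:
    doc = {s: {"bias_dps": [float(v) for v in b.bias],
               "computed_at": float(b.computed_at)}
           for s, b in biases.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_bias_file(path: str | Path) -> dict[str, GyroBias]:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return {s: GyroBias(bias=np.asarray(e["bias_dps"], dtype=float),
                        computed_at=float(e.get("computed_at", 0.0)))
            for s, e in doc.items()}


# -- calibration store --------------------------------------------------------

def _quat_list(q: Quaternion) -> list[float]:
    return [float(v) for v in q.as_array()]


def write_calibration(path: str | Path, state: CalibrationState) -> None:
    doc = {
        "target_heading": float(state.target_heading),
        "calibrated_at": float(state.calibrated_at),
        "sensors": {
            s: {
                "heading_correction": float(c.heading_correction),
                "initial_orientation": _quat_list(c.initial_orientation),
                "registration": _quat_list(c.registration),
                "bias_dps": [float(v) for v in c.bias.bias],
            } for s, c in state.sensors.items()},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_calibration(path: str | Path) -> CalibrationState:
    doc = yaml.safe_load(Path(path).read_text())
    sensors = {
        s: SensorCalibration(
            heading_correction=float(e["heading_correction"]),
            initial_orientation=Quaternion.from_array(e["initial_orientation"]),
            registration=Quaternion.from_array(e["registration"]),
            bias=GyroBias(np.asarray(e["bias_dps"], dtype=float)))
        for s, e in doc["sensors"].items()}
    return CalibrationState(target_heading=float(doc["target_heading"]),
                            sensors=sensors,
                            calibrated_at=float(doc.get("calibrated_at", 0.0)))
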
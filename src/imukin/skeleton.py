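"""Articulated skeleton model and forward kinematics.

The model is a tree of body segments rooted at the pelvis (the base segment a
pelvis sensor is always attached to).  Each joint connects a parent segment to
a child segment through 1-3 rotational degrees of freedom, each with a named
generalized coordinate, a rotation axis expressed in the parent frame, and
joint limits in degrees.  The pelvis itself carries three orientation
coordinates (tilt, list, rotation) treated as a joint from the world frame;
global translation is not modelled because joint kinematics depend only on
relative segment orientations.

The neutral standing pose defines the zero of every coordinate: at the
all-zero pose every segment orientation is the identity.  Joint degrees of
freedom are applied in their listed order as intrinsic rotations
(conventionally flexion, then adduction, then internal rotation), so a child
segment's world orientation is::

    q_child = q_parent * R(axis_1, angle_1) * R(axis_2, angle_2) * ...

Models are loaded from a YAML document; packaged defaults cover a 14-segment
full body, a lower-limb set, and an upper-limb set.  Degree-of-freedom axis
directions follow conventional biomechanics axes (flexion about mediolateral
z, adduction about anterior x, internal rotation about vertical y) and are
explicit in the config files, not hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .rotations import Quaternion

__all__ = [
    "Dof",
    "JointDef",
    "SkeletonModel",
    "Pose",
    "ModelValidationError",
    "load_model",
    "load_default_model",
    "forward_kinematics",
    "clamp_to_limits",
    "observable_coordinates",
]

ROOT_SEGMENT = "pelvis"
#: Name of the pseudo-joint carrying the pelvis orientation coordinates.
GROUND_JOINT = "ground_pelvis"

_AXIS_TOL = 1e-8


class ModelValidationError(ValueError):
    """A skeleton config violates a structural invariant."""


@dataclass(frozen=True)
class Dof:
    """One rotational degree of freedom of a joint."""

    name: str
    axis: np.ndarray  # unit 3-vector in the parent segment frame
    limit_lo: float
    limit_hi: float

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(axis)
        if abs(n - 1.0) > 1e-6:
            raise ModelValidationError(
                f"coordinate {self.name!r}: axis {axis.tolist()} is not unit-norm")
        object.__setattr__(self, "axis", axis)
        if not self.limit_lo < self.limit_hi:
            raise ModelValidationError(
                f"coordinate {self.name!r}: limit_lo must be < limit_hi")


@dataclass(frozen=True)
class JointDef:
    """A joint between two segments with 1-3 ordered degrees of freedom."""

    name: str
    parent_segment: str
    child_segment: str
    dofs: tuple[Dof, ...]
    locked: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.dofs) <= 3:
            raise ModelValidationError(
                f"joint {self.name!r}: needs 1-3 degrees of freedom")


@dataclass(frozen=True)
class Pose:
    """Generalized coordinates in degrees, ordered as in the model."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.names),):
            raise ValueError("pose length does not match coordinate names")
        object.__setattr__(self, "values", v)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def replace(self, **coords: float) -> "Pose":
        v = self.values.copy()
        for name, val in coords.items():
            if name not in self.names:
                raise KeyError(f"unknown coordinate {name!r}")
            v[self.names.index(name)] = val
        return Pose(self.names, v)

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}


class SkeletonModel:
    """Validated tree of segments with sensor mountings.

    Parameters
    ----------
    joints:
        Joint definitions; must include a joint whose parent is ``"ground"``
        and whose child is ``"pelvis"``, carrying the pelvis orientation
        coordinates.
    mounting:
        Fixed sensor-to-segment rotation per segment (identity when omitted).
    """

    def __init__(self, joints: Iterable[JointDef],
                 mounting: Mapping[str, Quaternion] | None = None,
                 name: str = "model"):
        self.name = name
        self.joints = tuple(joints)
        self._validate_tree()
        self.segments = tuple(j.child_segment for j in self._topo_joints)
        mounting = dict(mounting or {})
        for seg in mounting:
            if seg not in self.segments:
                raise ModelValidationError(f"mounting for unknown segment {seg!r}")
        self.mounting = {seg: mounting.get(seg, Quaternion.identity())
                         for seg in self.segments}
        names: list[str] = []
        for j in self._topo_joints:
            if j.locked:
                continue
            for d in j.dofs:
                if d.name in names:
                    raise ModelValidationError(
                        f"duplicate coordinate name {d.name!r}")
                names.append(d.name)
        self.coordinate_names: tuple[str, ...] = tuple(names)
        self._limits = {d.name: (d.limit_lo, d.limit_hi)
                        for j in self._topo_joints for d in j.dofs}

    def _validate_tree(self) -> None:
        parent_of: dict[str, str] = {}
        for j in self.joints:
            if j.child_segment in parent_of:
                raise ModelValidationError(
                    f"segment {j.child_segment!r} has more than one parent joint")
            parent_of[j.child_segment] = j.parent_segment
        roots = [j for j in self.joints if j.parent_segment == "ground"]
        if len(roots) != 1 or roots[0].child_segment != ROOT_SEGMENT:
            raise ModelValidationError(
                "model must have exactly one root joint ground -> pelvis")
        # walk up from every segment; a cycle or a dangling parent is an error
        for seg in parent_of:
            seen = set()
            cur = seg
            while cur != "ground":
                if cur in seen:
                    raise ModelValidationError(f"cycle detected at segment {cur!r}")
                seen.add(cur)
                if cur not in parent_of:
                    raise ModelValidationError(
                        f"segment {cur!r} is not connected to the pelvis root")
                cur = parent_of[cur]
        # topological (parent before child) joint order
        ordered: list[JointDef] = []
        placed = {"ground"}
        pending = list(self.joints)
        while pending:
            progressed = False
            for j in list(pending):
                if j.parent_segment in placed:
                    ordered.append(j)
                    placed.add(j.child_segment)
                    pending.remove(j)
                    progressed = True
            if not progressed:  # pragma: no cover - caught by walk above
                raise ModelValidationError("disconnected joints in model")
        self._topo_joints = tuple(ordered)

    # -- pose helpers -----------------------------------------------------

    def neutral_pose(self) -> Pose:
        return Pose(self.coordinate_names,
                    np.zeros(len(self.coordinate_names)))

    def pose_from_dict(self, coords: Mapping[str, float]) -> Pose:
        pose = self.neutral_pose()
        return pose.replace(**dict(coords))

    def limits(self, coordinate: str) -> tuple[float, float]:
        return self._limits[coordinate]

    def parent_of(self, segment: str) -> str:
        for j in self.joints:
            if j.child_segment == segment:
                return j.parent_segment
        raise KeyError(segment)


def forward_kinematics(model: SkeletonModel, pose: Pose) -> dict[str, Quaternion]:
    """World orientation of every segment at the given pose.

    The all-zero pose maps every segment to the identity orientation.
    Unknown coordinates in the pose raise ``KeyError``.
    """
    for n in pose.names:
        if n not in model.coordinate_names and n not in model._limits:
            raise KeyError(f"unknown coordinate {n!r}")
    values = pose.as_dict()
    orientations: dict[str, Quaternion] = {"ground": Quaternion.identity()}
    for j in model._topo_joints:
        q = orientations[j.parent_segment]
        for d in j.dofs:
            angle = 0.0 if j.locked else values.get(d.name, 0.0)
            if angle != 0.0:
                q = q * Quaternion.from_axis_angle(axis=d.axis, angle_deg=angle)
        orientations[j.child_segment] = q
    del orientations["ground"]
    return orientations


def clamp_to_limits(model: SkeletonModel, pose: Pose) -> Pose:
    """Clip every coordinate into its joint limits; in-range values pass
    through unchanged."""
    lo = np.array([model.limits(n)[0] for n in pose.names])
    hi = np.array([model.limits(n)[1] for n in pose.names])
    return Pose(pose.names, np.clip(pose.values, lo, hi))


def clamp_matrix(model: SkeletonModel, names: tuple[str, ...],
                 values: np.ndarray) -> np.ndarray:
    """Vectorized limit clamping of a (frames x coordinates) matrix."""
    lo = np.array([model.limits(n)[0] for n in names])
    hi = np.array([model.limits(n)[1] for n in names])
    return np.clip(values, lo, hi)


def observable_coordinates(model: SkeletonModel,
                           tracked_segments: Iterable[str]) -> tuple[str, ...]:
    """Coordinates constrained by sensors on ``tracked_segments``.

    A joint coordinate is observable when some tracked segment lies at or
    below the joint's child segment in the tree; coordinates of untracked
    branches stay at their warm-start values during inverse kinematics.
    """
    tracked = set(tracked_segments)
    ancestors: dict[str, set[str]] = {}
    for seg in model.segments:
        chain = set()
        cur = seg
        while cur != "ground":
            chain.add(cur)
            cur = "ground" if cur == ROOT_SEGMENT else model.parent_of(cur)
        ancestors[seg] = chain
    observable: list[str] = []
    for j in model._topo_joints:
        if j.locked:
            continue
        if any(j.child_segment in ancestors[t] for t in tracked):
            observable.extend(d.name for d in j.dofs)
    return tuple(observable)


# -- config loading -------------------------------------------------------

def _parse_dof(entry: Mapping) -> Dof:
    return Dof(name=str(entry["name"]),
               axis=np.asarray(entry["axis"], dtype=float),
               limit_lo=float(entry.get("limit_lo", -180.0)),
               limit_hi=float(entry.get("limit_hi", 180.0)))


def _parse_mounting(entry) -> Quaternion:
    if entry is None:
        return Quaternion.identity()
    axis = np.asarray(entry["axis"], dtype=float)
    return Quaternion.from_axis_angle(axis=axis, angle_deg=float(entry["angle_deg"]))


def load_model(source: str | Path) -> SkeletonModel:
    """Load and validate a skeleton model from a YAML document.

    ``source`` may be a path or the document text itself.
    """
    text = source
    if isinstance(source, Path) or (isinstance(source, str)
                                    and "\n" not in source
                                    and Path(source).exists()):
        text = Path(source).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "joints" not in doc:
        raise ModelValidationError("model config must define a 'joints' list")
    joints = []
    if "pelvis" in doc:
        joints.append(JointDef(
            name=GROUND_JOINT, parent_segment="ground", child_segment=ROOT_SEGMENT,
            dofs=tuple(_parse_dof(d) for d in doc["pelvis"])))
    for entry in doc["joints"]:
        joints.append(JointDef(
            name=str(entry["name"]),
            parent_segment=str(entry["parent"]),
            child_segment=str(entry["child"]),
            dofs=tuple(_parse_dof(d) for d in entry["dofs"]),
            locked=bool(entry.get("locked", False))))
    mounting = {seg: _parse_mounting(m)
                for seg, m in (doc.get("mountings") or {}).items()}
    return SkeletonModel(joints, mounting, name=str(doc.get("name", "model")))


def load_default_model(which: str = "full_body") -> SkeletonModel:
    """Load a packaged model config: ``full_body``, ``lower_limb`` or
    ``upper_limb``."""
    ref = resources.files("imukin").joinpath(f"models/{which}.yaml")
    return load_model(ref.read_text())
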
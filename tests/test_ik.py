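"""Orientation-tracking inverse kinematics: error geometry, frame solves
against FK round trips and brute-force grid oracles, and sequence behavior."""

import numpy as np
import pytest

from imukin.ik import (IKSettings, MotionRecord, angular_velocities,
                       orientation_error, solve_frame, solve_sequence)
from imukin.rotations import Quaternion, rotate_heading
from imukin.skeleton import Pose, forward_kinematics, load_model

from conftest import random_quaternion

ONE_DOF_YAML = """
name: hinge
pelvis:
  - {name: pelvis_tilt,     axis: [0, 0, 1], limit_lo: -90,  limit_hi: 90}
  - {name: pelvis_list,     axis: [1, 0, 0], limit_lo: -90,  limit_hi: 90}
  - {name: pelvis_rotation, axis: [0, 1, 0], limit_lo: -180, limit_hi: 180}
joints:
  - name: knee
    parent: pelvis
    child: shank
    dofs:
      - {name: knee_flexion, axis: [0, 0, 1], limit_lo: -5, limit_hi: 140}
"""

TWO_DOF_YAML = """
name: two_dof
pelvis:
  - {name: pelvis_tilt,     axis: [0, 0, 1], limit_lo: -90,  limit_hi: 90}
  - {name: pelvis_list,     axis: [1, 0, 0], limit_lo: -90,  limit_hi: 90}
  - {name: pelvis_rotation, axis: [0, 1, 0], limit_lo: -180, limit_hi: 180}
joints:
  - name: uj
    parent: pelvis
    child: thigh
    dofs:
      - {name: flex, axis: [0, 0, 1], limit_lo: -90, limit_hi: 90}
      - {name: add,  axis: [1, 0, 0], limit_lo: -60, limit_hi: 60}
"""


def objective(model, targets, names, values, settings):
    """The exact objective the solver minimizes, evaluated independently."""
    fk = forward_kinematics(model, Pose(tuple(names), np.asarray(values)))
    total = 0.0
    for seg, q in targets.items():
        e = orientation_error(q, fk[seg])
        total += settings.weight(seg) * float(e @ e)
    for i, n in enumerate(names):
        lo, hi = model.limits(n)
        v = values[i]
        viol = (v - hi) if v > hi else (lo - v) if v < lo else 0.0
        total += settings.constraint_weight * viol ** 2
    return total


class TestOrientationError:
    def test_zero_for_equal_rotations(self):
        q = Quaternion.from_axis_angle(axis=[1, 2, 3], angle_deg=40.0)
        assert np.allclose(orientation_error(q, q), 0.0, atol=1e-9)

    def test_closed_form_about_y(self):
        meas = Quaternion.from_axis_angle(axis=[0, 1, 0], angle_deg=30.0)
        e = orientation_error(meas, Quaternion.identity())
        assert np.allclose(e, [0.0, 30.0, 0.0], atol=1e-9)

    def test_antisymmetry_up_to_relative_rotation(self):
        """error(a,b) = -R error(b,a) where R is the relative rotation
        b^T a, checked numerically on random pairs."""
        rng = np.random.default_rng(31)
        for _ in range(50):
            a, b = random_quaternion(rng), random_quaternion(rng)
            e_ab = orientation_error(a, b)
            e_ba = orientation_error(b, a)
            rel = b.conjugate() * a
            assert np.allclose(e_ab, -rel.rotate(e_ba), atol=1e-6)

    def test_magnitude_bounded_by_180(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            e = orientation_error(random_quaternion(rng),
                                  random_quaternion(rng))
            assert 0.0 <= np.linalg.norm(e) <= 180.0 + 1e-9


class TestSolveFrame:
    def test_single_hinge_closed_form(self):
        model = load_model(ONE_DOF_YAML)
        target = Quaternion.from_axis_angle(axis=[0, 0, 1], angle_deg=30.0)
        targets = {"pelvis": Quaternion.identity(), "shank": target}
        pose, info = solve_frame(model, targets, model.neutral_pose())
        assert pose["knee_flexion"] == pytest.approx(30.0, abs=0.01)
        assert info["converged"]

    def test_fk_roundtrip_two_joint_chain(self):
        model = load_model(TWO_DOF_YAML)
        rng = np.random.default_rng(21)
        for _ in range(10):
            truth = model.neutral_pose().replace(
                flex=float(rng.uniform(-80, 80)),
                add=float(rng.uniform(-50, 50)),
                pelvis_tilt=float(rng.uniform(-30, 30)),
                pelvis_rotation=float(rng.uniform(-60, 60)))
            targets = forward_kinematics(model, truth)
            pose, _ = solve_frame(model, targets, model.neutral_pose())
            assert np.allclose(pose.values, truth.values, atol=0.1)

    def test_fk_roundtrip_full_body(self, full_body):
        rng = np.random.default_rng(2)
        names = full_body.coordinate_names
        margins = np.array([full_body.limits(n) for n in names])
        for _ in range(3):
            vals = rng.uniform(0.4 * margins[:, 0], 0.4 * margins[:, 1])
            truth = Pose(names, vals)
            targets = forward_kinematics(full_body, truth)
            pose, _ = solve_frame(full_body, targets, full_body.neutral_pose())
            assert np.abs(pose.values - truth.values).max() < 0.1

    def test_matches_grid_oracle_one_dof_noisy(self):
        """Noisy 1-DOF targets: solver minimum equals a 0.01-deg grid search
        of the identical objective within 0.05 deg."""
        model = load_model(ONE_DOF_YAML)
        settings = IKSettings()
        rng = np.random.default_rng(5)
        for _ in range(5):
            angle = float(rng.uniform(0, 120))
            noise_q = random_quaternion(rng)
            # blend a small random perturbation into the target
            perturb = Quaternion.from_axis_angle(
                axis=noise_q.to_axis_angle().axis, angle_deg=3.0)
            target = perturb * Quaternion.from_axis_angle(axis=[0, 0, 1],
                                                          angle_deg=angle)
            targets = {"pelvis": Quaternion.identity(), "shank": target}
            pose, _ = solve_frame(model, targets, model.neutral_pose(),
                                  settings, coordinates=("knee_flexion",))
            grid = np.arange(-5.0, 140.0 + 1e-9, 0.01)
            names = model.coordinate_names
            idx = names.index("knee_flexion")
            costs = []
            base = np.zeros(len(names))
            for g in grid:
                v = base.copy()
                v[idx] = g
                costs.append(objective(model, targets, names, v, settings))
            best = grid[int(np.argmin(costs))]
            assert pose["knee_flexion"] == pytest.approx(best, abs=0.05)

    def test_matches_grid_oracle_two_dof(self):
        """2-DOF chain vs a coarse-to-fine brute-force minimizer (1-deg grid
        refined to 0.01 deg) of the same objective."""
        model = load_model(TWO_DOF_YAML)
        settings = IKSettings()
        rng = np.random.default_rng(17)
        names = model.coordinate_names
        i_flex, i_add = names.index("flex"), names.index("add")
        for _ in range(3):
            truth_flex = float(rng.uniform(-70, 70))
            truth_add = float(rng.uniform(-45, 45))
            q_true = forward_kinematics(
                model, model.neutral_pose().replace(flex=truth_flex,
                                                    add=truth_add))["thigh"]
            perturb = Quaternion.from_axis_angle(axis=rng.normal(size=3),
                                                 angle_deg=2.0)
            targets = {"pelvis": Quaternion.identity(),
                       "thigh": perturb * q_true}
            pose, _ = solve_frame(model, targets, model.neutral_pose(),
                                  settings, coordinates=("flex", "add"))

            def cost(f, a):
                v = np.zeros(len(names))
                v[i_flex], v[i_add] = f, a
                return objective(model, targets, names, v, settings)

            # coarse 1-deg grid
            fs = np.arange(-90.0, 90.0 + 1e-9, 1.0)
            as_ = np.arange(-60.0, 60.0 + 1e-9, 1.0)
            costs = np.array([[cost(f, a) for a in as_] for f in fs])
            fi, ai = np.unravel_index(np.argmin(costs), costs.shape)
            f0, a0 = fs[fi], as_[ai]
            # refine on a 0.01-deg grid around the coarse minimum
            fs2 = np.arange(f0 - 1.5, f0 + 1.5 + 1e-9, 0.01)
            as2 = np.arange(a0 - 1.5, a0 + 1.5 + 1e-9, 0.01)
            costs2 = np.array([[cost(f, a) for a in as2] for f in fs2])
            fi2, ai2 = np.unravel_index(np.argmin(costs2), costs2.shape)
            assert pose["flex"] == pytest.approx(fs2[fi2], abs=0.05)
            assert pose["add"] == pytest.approx(as2[ai2], abs=0.05)

    def test_limit_penalty_and_clamp(self):
        model = load_model(ONE_DOF_YAML)
        # target beyond the upper joint limit: solution is clamped to it
        target = Quaternion.from_axis_angle(axis=[0, 0, 1], angle_deg=170.0)
        targets = {"pelvis": Quaternion.identity(), "shank": target}
        pose, _ = solve_frame(model, targets, model.neutral_pose())
        assert pose["knee_flexion"] <= 140.0 + 1e-9
        assert pose["knee_flexion"] > 135.0

    def test_unknown_segment_rejected(self):
        model = load_model(ONE_DOF_YAML)
        with pytest.raises(KeyError):
            solve_frame(model, {"nope": Quaternion.identity()},
                        model.neutral_pose())


class TestSolveSequence:
    @staticmethod
    def _passthrough_calibration(model, segments):
        from imukin.calibration import CalibrationState, SensorCalibration
        from imukin.fusion import GyroBias
        sensors = {s: SensorCalibration(
            heading_correction=0.0,
            initial_orientation=Quaternion.identity(),
            registration=model.mounting[s],
            bias=GyroBias.zero()) for s in segments}
        return CalibrationState(target_heading=0.0, sensors=sensors)

    def test_standing_fixed_point(self, lower_limb):
        cal = self._passthrough_calibration(lower_limb, lower_limb.segments)
        frames = [(i / 30.0, {s: Quaternion.identity()
                              for s in lower_limb.segments})
                  for i in range(30)]
        rec = solve_sequence(lower_limb, frames, cal)
        assert np.abs(rec.data).max() < 0.5

    def test_tracks_fk_of_known_motion(self, lower_limb):
        cal = self._passthrough_calibration(lower_limb, lower_limb.segments)
        rng = np.random.default_rng(3)
        names = lower_limb.coordinate_names
        t = np.arange(60) / 30.0
        truth = np.zeros((len(t), len(names)))
        truth[:, names.index("hip_flexion_r")] = 25 * np.sin(2 * np.pi * t)
        truth[:, names.index("knee_flexion_r")] = \
            30 + 30 * np.sin(2 * np.pi * t - 1.2)
        frames = []
        for i, ti in enumerate(t):
            fk = forward_kinematics(lower_limb, Pose(names, truth[i]))
            frames.append((float(ti), fk))
        rec = solve_sequence(lower_limb, frames, cal)
        assert np.abs(rec.data - truth).max() < 0.1

    def test_deterministic(self, lower_limb):
        cal = self._passthrough_calibration(lower_limb, lower_limb.segments)
        rng = np.random.default_rng(4)
        frames = []
        for i in range(10):
            pose = Pose(lower_limb.coordinate_names,
                        rng.uniform(-10, 10,
                                    len(lower_limb.coordinate_names)))
            frames.append((i / 30.0,
                           forward_kinematics(lower_limb, pose)))
        a = solve_sequence(lower_limb, frames, cal)
        b = solve_sequence(lower_limb, frames, cal)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.time, b.time)

    def test_global_yaw_moves_only_pelvis_heading(self, lower_limb):
        """Applying one global yaw to every target leaves non-pelvis joint
        coordinates unchanged (pelvis is the base segment)."""
        cal = self._passthrough_calibration(lower_limb, lower_limb.segments)
        names = lower_limb.coordinate_names
        pose = lower_limb.neutral_pose().replace(
            hip_flexion_r=20.0, knee_flexion_l=45.0, ankle_flexion_r=-5.0)
        fk = forward_kinematics(lower_limb, pose)
        frames_a = [(0.0, fk)]
        yawed = {s: rotate_heading(q, 40.0) for s, q in fk.items()}
        frames_b = [(0.0, yawed)]
        rec_a = solve_sequence(lower_limb, frames_a, cal)
        rec_b = solve_sequence(lower_limb, frames_b, cal)
        for n in names:
            if n == "pelvis_rotation":
                assert rec_b.column(n)[0] - rec_a.column(n)[0] == \
                    pytest.approx(40.0, abs=0.05)
            else:
                assert rec_b.column(n)[0] == \
                    pytest.approx(rec_a.column(n)[0], abs=0.05), n

    def test_warm_start_reduces_iterations(self, lower_limb):
        cal = self._passthrough_calibration(lower_limb, lower_limb.segments)
        names = lower_limb.coordinate_names
        t = np.arange(30) / 30.0
        frames = []
        for ti in t:
            pose = lower_limb.neutral_pose().replace(
                hip_flexion_r=25 * np.sin(2 * np.pi * ti),
                knee_flexion_r=30 + 25 * np.sin(2 * np.pi * ti - 1.0))
            frames.append((float(ti), forward_kinematics(lower_limb, pose)))
        warm_iters, cold_iters = [], []
        warm = lower_limb.neutral_pose()
        for ti, fk in frames[1:]:
            _, info_w = solve_frame(lower_limb, fk, warm)
            warm_pose, _ = solve_frame(lower_limb, fk, warm)
            warm = warm_pose
            _, info_c = solve_frame(lower_limb, fk,
                                    lower_limb.neutral_pose())
            warm_iters.append(info_w["iterations"])
            cold_iters.append(info_c["iterations"])
        assert np.median(warm_iters) <= np.median(cold_iters)


class TestMotionRecord:
    def test_column_order_and_access(self):
        rec = MotionRecord(time=np.array([0.0, 0.1]),
                           data=np.array([[1.0, 2.0], [3.0, 4.0]]),
                           names=("a", "b"), rate=10.0)
        assert np.array_equal(rec.column("b"), [2.0, 4.0])
        assert len(rec) == 2

    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError):
            MotionRecord(time=np.array([0.0, 0.0]),
                         data=np.zeros((2, 1)), names=("a",), rate=10.0)

    def test_angular_velocity_of_linear_ramp(self):
        t = np.arange(50) / 10.0
        data = (5.0 * t)[:, None]
        rec = MotionRecord(time=t, data=data, names=("a",), rate=10.0)
        vel = angular_velocities(rec)
        assert np.allclose(vel.column("a"), 5.0, atol=1e-9)
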
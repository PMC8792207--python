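# imukin

Magnetometer-free inertial motion capture: joint kinematics in real time
from body-worn IMUs (3-axis accelerometer + 3-axis gyroscope), with a
synthetic-data simulator for end-to-end validation at the desk.

## How it works

Each body segment carries one IMU. Per sensor, a **Mahony passive
complementary filter** fuses gyroscope integration with the accelerometer's
gravity reference: the gyro provides high-bandwidth orientation, the
accelerometer corrects low-frequency tilt drift through a
proportional–integral feedback term (default gains kp = 1, ki = 0.3). No
magnetometer is used, so the rotation about the vertical (heading) is never
corrected by the filter; instead a **standing-pose calibration** aligns all
sensors to a common heading (circular mean), estimates each gyroscope's
constant bias from a 10-s stationary recording, and registers each sensor to
its body segment so that the standing pose maps to the model's neutral pose.

Kinematics come from **orientation-tracking inverse kinematics** on an
articulated skeleton (tree of segments connected by 1–3-DOF rotational
joints with limits). Per frame, a damped Gauss–Newton solver minimizes the
weighted sum of squared axis-angle discrepancies between measured and
modelled segment orientations, plus a quadratic penalty on joint-limit
violations, warm-started from the previous frame. A **two-stage streaming
pipeline** (per-sample fusion feeding a fixed-rate IK stage through a
latest-value exchange) runs either online or as an offline batch; at matched
rates the two modes are bit-identical.

A **synthetic IMU simulator** closes the loop: it generates gait-like joint
trajectories, derives exact specific-force and angular-rate streams from the
model's forward kinematics, and adds white sensor noise (accelerometer stds
0.0155/0.0244/0.254 m/s², gyroscope stds 0.0742/0.0583/0.0369 deg/s), so the
full pipeline can be scored against known ground truth.

## Conventions

- World frame: x anterior (direction of progression), y up, z right;
  gravity is (0, −9.81, 0) m/s².
- Quaternions are scalar-first and map sensor/segment frames to the world.
- Angles in degrees throughout the public API; angular rates in deg/s.
- Motion files are tab-delimited `.sto`/`.mot` text (`endheader`, `time`
  first column, `inDegrees=yes`); IMU streams are CSV
  (`time_s, ax, ay, az, gx, gy, gz`).

Three skeleton models ship with the package (YAML, user-extensible):
`lower_limb` (pelvis + both legs, 13 coordinates), `upper_limb` and
`full_body` (26 coordinates).

## Worked example

Simulate a standing capture and a 30-s walk, calibrate, track online at
30 Hz, and score against the simulator's ground truth:

```sh
imukin simulate --motion static --duration 12 --seed 1 --out static/
imukin simulate --motion gait   --duration 30 --seed 2 --out walk/
imukin calibrate-gyro --data static/ --out bias.yaml
imukin calibrate-pose --data static/ --bias bias.yaml --out calibration.yaml
imukin track --data walk/ --calibration calibration.yaml \
             --mode online --ik-rate 30 --out motion.sto
imukin evaluate motion.sto walk/truth.sto
imukin fpa motion.sto
```

Output of the last two commands (exact numbers for these seeds):

```
     coordinate  rmse_deg  pearson_r
    pelvis_tilt     0.017        NaN
    pelvis_list     0.226      0.999
pelvis_rotation     0.102      1.000
  hip_flexion_r     0.553      1.000
hip_adduction_r     2.011      0.833
 hip_rotation_r     5.648      0.702
 knee_flexion_r     1.522      0.998
ankle_flexion_r     0.261      1.000
  hip_flexion_l     0.536      1.000
hip_adduction_l     2.243      0.775
 hip_rotation_l     6.186      0.661
 knee_flexion_l     1.400      0.998
ankle_flexion_l     0.267      1.000
overall RMSE: 1.613 deg
foot progression angle (calcn_r): +6.78 deg (toe-out positive)
```

Sagittal-plane angles (flexion/extension) track within ~0.3–1.5°;
transverse-plane angles (hip rotation) are the least accurate because,
without a magnetometer, each sensor's heading drifts independently with
integrated gyro noise — the characteristic limitation of magnetometer-free
capture. A `NaN` correlation flags a coordinate whose reference is constant
(zero variance). The same workflow is available from Python; see
`imukin`'s top-level API (`synthesize`, `calibrate`, `run_online`,
`compare`, …) and `docs/methods.md` for the underlying math.

## Limitations

- No magnetometer: absolute heading is unobservable; all headings are
  relative to the standing calibration, and transverse-plane angles drift
  slowly with gyro noise.
- The simulator generates angular motion only (no linear acceleration), so
  it exercises the orientation pipeline, not accelerometer disturbance
  rejection; the accelerometer gate (0.5–1.5 g) handles the latter on real
  data.
- Gait-event detection is out of scope; cycle averaging and per-step foot
  progression angles take externally supplied event times.
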
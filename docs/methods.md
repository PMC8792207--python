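# Methods

This note documents the algorithms, conventions and numerical choices
implemented in `imukin`. Symbols: quaternions are scalar-first unit
quaternions mapping a local frame to the world frame; `⊗` is quaternion
composition; angles are degrees unless marked rad.

## Frames and rotations (`imukin.rotations`)

World frame: x anterior, y up, z right. Gravity is g = (0, −9.81, 0) m/s².
`Quaternion` implements composition, vector rotation, axis-angle and
rotation-vector maps, and matrix conversion (Shepperd's method for
matrix → quaternion). Relative angles use
`2·atan2(‖vec(q_rel)‖, |w_rel|)`, which is accurate near identity where the
arccosine form loses precision.

The *heading* of a rotation is the yaw of its rotated forward axis:
`ψ = atan2(−f_z, f_x)` with `f = q·x̂`; it is undefined (raised as
`DegenerateHeadingError`) when the rotated forward axis is within 1e-6 of
vertical. `rotate_heading(q, Δψ)` pre-multiplies a world-yaw, changing the
heading by exactly Δψ while preserving the inclination of the vertical
axis.

## Skeleton model (`imukin.skeleton`)

A model is a tree of segments rooted at the pelvis through a 3-DOF
pseudo-joint (`ground_pelvis`). Each joint carries 1–3 rotational DOFs,
each with a unit axis in the parent frame and hard limits. Forward
kinematics composes intrinsic axis-angle rotations in DOF order down the
tree; the zero pose is the standing neutral (all segment orientations are
identity). Sensor mountings (constant segment → sensor rotations) default to
identity and may be declared per segment in the model YAML.
`observable_coordinates` restricts a solve to coordinates on paths between
tracked segments, so untracked branches never move.

## Synthetic IMU data (`imukin.imu_sim`)

Given a joint-space trajectory q(t) (coordinate → angle function), each
tracked segment's sensor orientation is `q_s(t) = FK(q(t)) ⊗ mounting`. The
simulator outputs, per sample:

- specific force `a = q_s⁻¹ · (−g)` — angular motion only, no linear
  acceleration term; this isolates the orientation pipeline,
- angular rate from the central-differenced quaternion logarithm,
  `ω_i = log(q_{i−1}⁻¹ ⊗ q_{i+1}) / (t_{i+1} − t_{i−1})` (one-sided at the
  ends), converted to deg/s,
- additive white Gaussian noise with per-axis stds
  accel (0.0155, 0.0244, 0.254) m/s², gyro (0.0742, 0.0583, 0.0369) deg/s,
  plus an optional constant gyro bias. Per-sensor generators are spawned
  from one `SeedSequence` so streams are independent but reproducible.

Gait trajectories are sinusoids with a common period: knee lags hip by a
quarter cycle, ankle by a half; left-side coordinates are a half cycle out
of phase with the right. Amplitudes ramp in over the first 2 s with a
smoothstep so motion starts from the standing pose that calibration
assumes.

## Sensor fusion (`imukin.fusion`)

The Mahony passive complementary filter per sensor, at sample rate 1/dt:

```
v̂ = q⁻¹ · ŷ                      predicted gravity-reaction direction
e  = â × v̂                       innovation (â = normalized accelerometer)
i  ← clamp(i + ki·e·dt)          integral term, rad/s
ω  = radians(gyro − bias) + kp·e + i
q  ← q ⊗ exp(ω·dt)               quaternion exponential, renormalized
```

Defaults kp = 1, ki = 0.3. The accelerometer contributes no correction when
its norm is outside 0.5–1.5 g (linear-acceleration gate). The integral term
models residual gyro bias, which after the 10-s bias calibration is far
below 1 deg/s, so its norm is clamped to 1 deg/s — standard anti-windup
that keeps a large initial orientation error from charging the integrator
and delaying settling; settling from a 30° error takes ≈ 2.3 s at 100 Hz.
Without a magnetometer, the component of error about the world vertical is
never corrected.

For run-level (batch) integration, consecutive gyro samples are averaged in
pairs (`trapezoid_rates`) before stepping, removing most of the first-order
truncation error at low sample rates; the per-step filter contract is
unchanged, and online/offline runs remain bit-identical because both paths
apply the same averaging.

Gyro bias is the per-axis mean over the first 10 s of a stationary
recording. At the noise levels above, successive 10-s estimates fluctuate
by only a few thousandths of a deg/s (see `scripts/acceptance.py`).

## Standing-pose calibration (`imukin.calibration`)

From a stationary standing recording (≥ 10 s for bias, ≥ 3 s for
orientation):

1. Run the filter per sensor to a static orientation estimate `q_i`.
2. Compute each sensor's heading `ψ_i` and the circular mean `ψ̄`; the
   per-sensor correction `Δψ_i = ψ̄ − ψ_i` rotates every sensor to the
   common target heading.
3. Registration: `r_i = corrected_q_i⁻¹ ⊗ (FK_neutral(segment) ⊗ mounting)`,
   the constant rotation that maps the corrected sensor orientation to its
   segment at the standing pose.

At run time a segment's measured orientation is
`rotate_heading(q_raw, Δψ_i) ⊗ r_i ⊗ mounting⁻¹`; by construction the
standing pose reproduces the model's neutral pose to machine precision, and
constant mounting errors are absorbed into `r_i`.

## Inverse kinematics (`imukin.ik`)

Per frame, with measured segment orientations `m_s` and model orientations
`FK_s(x)`:

```
J(x) = Σ_s w_s ‖e_s(x)‖²  +  w_c Σ_i max(0, viol_i(x))²
e_s  = axis·angle of FK_s(x)⁻¹ ⊗ m_s   (degrees)
```

with unit tracking weights and constraint weight w_c = 10 on joint-limit
violations, followed by a hard clamp. The solver is a damped Gauss–Newton
(Levenberg) iteration: numerical Jacobian (forward differences, 0.01° step),
solve `(JᵀJ + λI)Δ = −Jᵀr`, accept only non-increasing steps (λ×10 retry on
rejection, λ/3 on acceptance), stop when the largest coordinate step falls
below 0.001 rad or the relative objective decrease falls below 0.001.

Cold starts use a closed-form initial guess: for each joint with both ends
targeted, the relative target rotation is peeled onto the joint's axes in
order by repeated twist extraction
(`θ = 2·atan2(vec(q)·axis, w)`). This places the solve in the basin of the
global minimum — avoiding mirrored local minima of 3-DOF chains — and is
polished to the exact answer in ~3 iterations. Across a sequence each frame
warm-starts from the previous solution, which also selects the continuous
branch among equivalent minima; a non-converged frame carries the previous
pose forward with a warning rather than stalling.

## Streaming pipeline (`imukin.pipeline`)

Two logical stages: stage 1 consumes every IMU sample and keeps one filter
per sensor current; stage 2 fires at the computation rate (default 30 Hz),
snapshots the newest orientation of every sensor through a single-slot
*latest-value exchange* (writes never block; reads return the newest frame;
frames may be skipped but never reordered) and solves one IK frame. At desk
scale the contract executes single-threaded on a simulated clock. Offline
mode runs fusion then IK over every recorded sample; when the computation
rate equals the stream rate the two modes produce bit-identical pose data.

## Metrics (`imukin.metrics`)

Per-coordinate RMSE and Pearson correlation (NaN for zero-variance
columns), a sliding-window drift curve (default 10-s windows, half-window
hop), gait-cycle averaging onto a 101-point 0–100% base from supplied event
times, and the foot progression angle from virtual heel/toe markers fixed
in the foot frame (defaults heel (−0.05, −0.04, 0) m, toe (0.15, −0.04,
0) m): the signed angle between the horizontal projection of the
heel-to-toe vector and the direction of progression, toe-out positive. The
reference record is always resampled onto the estimate's timestamps, never
the reverse, so a decimated online clock cannot fabricate estimate samples.

## Scope and limitations

- The simulator omits linear acceleration and soft-tissue artifact; it
  validates the orientation pipeline, not accelerometer disturbance
  rejection on real data.
- Absolute heading is undefined; all results are relative to the
  calibration heading, and transverse-plane angles accumulate slow
  heading drift from integrated gyro noise.
- Joint limits are enforced by penalty plus final clamp, not by a
  constrained solver; with consistent data the penalty is inactive.
- Gait events (cycle boundaries, step windows) are inputs, not outputs.
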
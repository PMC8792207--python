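# Full-body skeleton: 14 tracked segments, 26 generalized coordinates.
# Axes are in the parent segment frame (x anterior, y up, z right) and follow
# conventional biomechanics conventions: flexion about the mediolateral axis,
# adduction about the anterior axis, internal rotation about the vertical
# axis.  The neutral standing pose (arms at the sides) is the zero of every
# coordinate.  Limits are generous defaults; override per deployment.
name: full_body
pelvis:
  - {name: pelvis_tilt,     axis: [0, 0, 1], limit_lo: -90,  limit_hi: 90}
  - {name: pelvis_list,     axis: [1, 0, 0], limit_lo: -90,  limit_hi: 90}
  - {name: pelvis_rotation, axis: [0, 1, 0], limit_lo: -180, limit_hi: 180}
joints:
  - name: hip_r
    parent: pelvis
    child: femur_r
    dofs:
      - {name: hip_flexion_r,   axis: [0, 0, 1],  limit_lo: -120, limit_hi: 120}
      - {name: hip_adduction_r, axis: [1, 0, 0],  limit_lo: -50,  limit_hi: 50}
      - {name: hip_rotation_r,  axis: [0, 1, 0],  limit_lo: -60,  limit_hi: 60}
  - name: knee_r
    parent: femur_r
    child: tibia_r
    dofs:
      - {name: knee_flexion_r, axis: [0, 0, -1], limit_lo: 0, limit_hi: 140}
  - name: ankle_r
    parent: tibia_r
    child: calcn_r
    dofs:
      - {name: ankle_flexion_r, axis: [0, 0, 1], limit_lo: -50, limit_hi: 50}
  - name: hip_l
    parent: pelvis
    child: femur_l
    dofs:
      - {name: hip_flexion_l,   axis: [0, 0, 1],  limit_lo: -120, limit_hi: 120}
      - {name: hip_adduction_l, axis: [-1, 0, 0], limit_lo: -50,  limit_hi: 50}
      - {name: hip_rotation_l,  axis: [0, -1, 0], limit_lo: -60,  limit_hi: 60}
  - name: knee_l
    parent: femur_l
    child: tibia_l
    dofs:
      - {name: knee_flexion_l, axis: [0, 0, -1], limit_lo: 0, limit_hi: 140}
  - name: ankle_l
    parent: tibia_l
    child: calcn_l
    dofs:
      - {name: ankle_flexion_l, axis: [0, 0, 1], limit_lo: -50, limit_hi: 50}
  - name: back
    parent: pelvis
    child: torso
    dofs:
      - {name: lumbar_extension, axis: [0, 0, 1], limit_lo: -90, limit_hi: 90}
      - {name: lumbar_bending,   axis: [1, 0, 0], limit_lo: -60, limit_hi: 60}
      - {name: lumbar_rotation,  axis: [0, 1, 0], limit_lo: -60, limit_hi: 60}
  - name: shoulder_r
    parent: torso
    child: humerus_r
    dofs:
      - {name: arm_flexion_r,   axis: [0, 0, 1],  limit_lo: -90,  limit_hi: 180}
      - {name: arm_adduction_r, axis: [1, 0, 0],  limit_lo: -120, limit_hi: 120}
      - {name: arm_rotation_r,  axis: [0, 1, 0],  limit_lo: -90,  limit_hi: 90}
  - name: elbow_r
    parent: humerus_r
    child: ulna_r
    dofs:
      - {name: elbow_flexion_r, axis: [0, 0, 1], limit_lo: 0, limit_hi: 150}
  - name: wrist_r
    parent: ulna_r
    child: hand_r
    dofs:
      - {name: wrist_flexion_r, axis: [0, 0, 1], limit_lo: -70, limit_hi: 70}
  - name: shoulder_l
    parent: torso
    child: humerus_l
    dofs:
      - {name: arm_flexion_l,   axis: [0, 0, 1],  limit_lo: -90,  limit_hi: 180}
      - {name: arm_adduction_l, axis: [-1, 0, 0], limit_lo: -120, limit_hi: 120}
      - {name: arm_rotation_l,  axis: [0, -1, 0], limit_lo: -90,  limit_hi: 90}
  - name: elbow_l
    parent: humerus_l
    child: ulna_l
    dofs:
      - {name: elbow_flexion_l, axis: [0, 0, 1], limit_lo: 0, limit_hi: 150}
  - name: wrist_l
    parent: ulna_l
    child: hand_l
    dofs:
      - {name: wrist_flexion_l, axis: [0, 0, 1], limit_lo: -70, limit_hi: 70}
# Sensor-to-segment mountings default to identity; list non-trivial ones here,
# e.g. a sensor strapped with its case rotated 90 degrees about the segment's
# long axis:
# mountings:
#   tibia_r: {axis: [0, 1, 0], angle_deg: 90}
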
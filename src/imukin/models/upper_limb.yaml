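# Upper-limb skeleton: pelvis (base), trunk and both arms
# (8 segments, 16 coordinates).  Same axis conventions as full_body.yaml.
name: upper_limb
pelvis:
  - {name: pelvis_tilt,     axis: [0, 0, 1], limit_lo: -90,  limit_hi: 90}
  - {name: pelvis_list,     axis: [1, 0, 0], limit_lo: -90,  limit_hi: 90}
  - {name: pelvis_rotation, axis: [0, 1, 0], limit_lo: -180, limit_hi: 180}
joints:
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
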
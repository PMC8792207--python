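# Lower-limb skeleton: pelvis plus both legs (7 segments, 13 coordinates).
# Same axis conventions as full_body.yaml.
name: lower_limb
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
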
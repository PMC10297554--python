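- name: v_sR
  mean: 0.0
  sd: 0.0
  min: 0.5
  max: 2.0
  kind: uniform
- name: v_inR
  mean: 0.0
  sd: 0.0
  min: 0.5
  max: 2.0
  kind: uniform
- name: v_sVR
  mean: 0.0
  sd: 0.0
  min: 0.5
  max: 2.0
  kind: uniform
- name: v_inVR
  mean: 0.0
  sd: 0.0
  min: 0.5
  max: 2.0
  kind: uniform
- name: v_nc
  mean: 0.0
  sd: 0.0
  min: 0
  max: 30
  kind: integer_uniform
- name: asht
  mean: 0.0
  sd: 0.0
  min: 0.01
  max: 0.15
  kind: uniform
- name: RQ
  mean: 0.8
  sd: 0.05
  min: 0.7
  max: 1.0
  kind: truncated_normal
- name: VO2
  mean: 0.25
  sd: 0.05
  min: 0.15
  max: 0.5
  kind: truncated_normal
- name: VD_phys
  mean: 0.15
  sd: 0.03
  min: 0.08
  max: 0.3
  kind: truncated_normal
- name: CO
  mean: 5.0
  sd: 1.0
  min: 2.5
  max: 9.0
  kind: truncated_normal
- name: IE_ratio
  mean: 0.0
  sd: 0.0
  min: 0.33
  max: 1.0
  kind: uniform
- name: Hb
  mean: 9.15
  sd: 1.17
  min: 6
  max: 12
  kind: truncated_normal
- name: FiO2
  mean: 41.08
  sd: 12.39
  min: 20
  max: 100
  kind: truncated_normal
- name: PEEP
  mean: 8.64
  sd: 3.15
  min: 0
  max: 24
  kind: truncated_normal
- name: P_EI
  mean: 21.68
  sd: 5.76
  min: 0
  max: 40
  kind: truncated_normal
- name: SvO2
  mean: 68.81
  sd: 11.03
  min: 30
  max: 100
  kind: truncated_normal
- name: RR
  mean: 20.83
  sd: 5.73
  min: 10
  max: 40
  kind: truncated_normal
- name: Vt
  mean: 463.8
  sd: 115.13
  min: 220
  max: 840
  kind: truncated_normal
- name: BE_a
  mean: 1.37
  sd: 4.42
  min: -15
  max: 15
  kind: truncated_normal
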
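# Default nuclide table for the Ac-225 recoil-daughter analysis.
# Half-lives are the values used throughout the package; replace with
# evaluated-data values if higher precision is required.
- name: Ac-225
  half_life_value: 10
  half_life_unit: d
  branching: 1.0
- name: Fr-221
  half_life_value: 4.8
  half_life_unit: min
  gamma_line_kev: 218
  window_kev: [170, 270]
  branching: 1.0
- name: Bi-213
  half_life_value: 45.6
  half_life_unit: min
  gamma_line_kev: 440
  window_kev: [380, 520]
  branching: 1.0
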
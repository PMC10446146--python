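# Reasonable worst-case room scenario: 20 m3 dwelling room at 0.5 1/h,
# two purifiers (10 m3/h each, three 90 cm2 coated honeycombs each)
# represented as one combined bank, emitting at the measured release-factor
# upper bound with negligible particle filtration.
room:
  volume_m3: 20.0
  ach_per_h: 0.5
  lambda_dep_per_h: 0.0
  outdoor_conc_ng_m3: 0.0
  penetration: 1.0
purifiers:
  - flow_m3_h: 20.0
    n_units: 6
    area_per_unit_m2: 0.009
    release_factor_ng_m2_m3: 0.185
    filtration_efficiency: 0.0
oels:
  - name: "proposed nano-TiO2 OEL, low end (8 h TWA)"
    value_ug_m3: 0.8
  - name: "proposed nano-TiO2 OEL, low end (24 h population)"
    value_ug_m3: 0.8
    averaging: 24h_population
  - name: "proposed nano-TiO2 OEL, high end (8 h TWA)"
    value_ug_m3: 5000.0
duration_h: 10.0
initial_conc_ng_m3: 0.0
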
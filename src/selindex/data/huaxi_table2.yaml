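# Genetic parameters for the Huaxi cattle study herd (2,992 cows):
# 12-month body weight (WEI-12) and daily milk yield (DMY), with the nine
# built-in sensitivity scenarios C1-C9.  Loading this file reproduces
# selindex.huaxi_parameters() and selindex.builtin_scenarios().
traits:
  - name: WEI-12
    unit: kg
    n_records: 2992
    mean: 357.15
    sd: 28.1
    var_P: 789.61
    var_A: 11.21
    h2: 0.39
  - name: DMY
    unit: kg
    n_records: 2992
    mean: 28.50
    sd: 5.9
    var_P: 34.81
    var_A: 2.25
    h2: 0.39
pairs:
  - trait_i: WEI-12
    trait_j: DMY
    r_A: -0.15
    cov_G: -0.75
    r_E: 0.0
scenarios:
  - {id: C1, p: 0.10, economic_weights: [0.5, 1.0]}
  - {id: C2, p: 0.20, economic_weights: [0.5, 1.0]}
  - {id: C3, p: 0.10, economic_weights: [1.0, 0.5]}
  - {id: C4, p: 0.20, economic_weights: [1.0, 0.5]}
  - {id: C5, p: 0.10, economic_weights: [1.0, 1.0]}
  - {id: C6, p: 0.20, economic_weights: [1.0, 1.0]}
  - {id: C7, p: 0.10, economic_weights: [0.5, 1.0], h2_modifier: 1.10}
  - {id: C8, p: 0.10, economic_weights: [0.5, 1.0], h2_modifier: 0.90}
  - {id: C9, p: 0.10, economic_weights: [0.5, 1.0], r_A_override: -0.20}
generations: 4
h2_source: printed
relationship: identity
# Four-generation desired-gains targets (kg): the per-trait cumulative
# gains of the baseline condition C1.
desired_gains: [0.4331, 0.1525]
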
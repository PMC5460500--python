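a0: 0.010610536994047473
a1: 0.1321661807525725
a2: 5.4516784074074955
adenoma_risk_anchors_advanced:
  multipliers:
  - 0.003
  - 0.005
  - 0.055999999999999994
  - 0.175
  - 0.36000000000000004
  - 0.48999999999999994
  quantiles:
  - 0.0
  - 0.66
  - 0.77
  - 0.86
  - 0.93
  - 1.0
adenoma_risk_anchors_early:
  multipliers:
  - 0.02
  - 0.05
  - 0.35
  - 0.36000000000000004
  - 0.42
  quantiles:
  - 0.0
  - 0.87
  - 0.92
  - 0.97
  - 1.0
b0: 0.6087853435333626
b1: 0.015952029042526655
b2: 1.6117403154065393
c0: 0.4906070522720569
c1: 0.014655961737210718
c2: 1.9244383703433403
direct_cancer_risk:
- 1.1718292236328126e-05
- 1.1718292236328126e-05
- 1.1718292236328126e-05
- 1.1718292236328126e-05
- 1.1718292236328126e-05
- 1.1718292236328126e-05
- 2.343658447265625e-05
- 3.5154876708984384e-05
- 3.5154876708984384e-05
- 3.5154876708984384e-05
- 4.68731689453125e-05
- 4.68731689453125e-05
- 5.859146118164063e-05
dwell_variant: 19
individual_risk_anchors:
  multipliers:
  - 0.02
  - 0.15
  - 0.6
  - 1.8
  - 4.5
  - 12.0
  quantiles:
  - 0.0
  - 0.4
  - 0.7
  - 0.9
  - 0.98
  - 1.0
rectum_factors:
- 1.3
- 9.45132597768411
schema_version: 1
sex_factors:
- 1.352808548591109
- 1.1088043474904001
- 0.9639557936737742
sojourn_mean_y: 3.0
sojourn_sd_y: 0.5
stage_cancer_risk:
- 0.0010068611594266548
- 0.0020137223188533095
- 0.004027444637706619
- 0.010068611594266549
- 0.040274446377066196
stage_dwell_weights:
- 0.1785
- 0.2182
- 0.2834
- 0.32
stage_progression:
- 1.0
- 1.0
- 1.0
- 1.0
- 1.0
- 1.0
stage_regression:
- 0.014
- 0.01
- 0.007
- 0.005
- 0.004
- 0.002
symptomatic_stage_dist:
- 0.12
- 0.32
- 0.31
- 0.25
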
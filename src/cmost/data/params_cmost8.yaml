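a0: 0.010824267705111554
a1: 0.1291407302718569
a2: 5.143334886313898
adenoma_risk_anchors_advanced:
  multipliers:
  - 0.003
  - 0.005
  - 0.096
  - 0.5599999999999999
  - 1.9800000000000002
  - 3.9199999999999995
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
  - 0.6
  - 1.7600000000000002
  - 3.36
  quantiles:
  - 0.0
  - 0.87
  - 0.92
  - 0.97
  - 1.0
b0: 0.5861048740560627
b1: 0.014402524775914532
b2: 1.9039134961408997
c0: 0.520078142294142
c1: 0.013780839699161782
c2: 1.929078365791142
direct_cancer_risk:
- 5.5801391601562495e-06
- 5.5801391601562495e-06
- 5.5801391601562495e-06
- 5.5801391601562495e-06
- 5.5801391601562495e-06
- 5.5801391601562495e-06
- 1.1160278320312499e-05
- 1.6740417480468753e-05
- 1.6740417480468753e-05
- 1.6740417480468753e-05
- 2.2320556640624998e-05
- 2.2320556640624998e-05
- 2.7900695800781247e-05
dwell_variant: 8
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
- 9.090483472314059
schema_version: 1
sex_factors:
- 1.352808548591109
- 1.1088043474904001
- 0.9639557936737742
sojourn_mean_y: 3.0
sojourn_sd_y: 0.5
stage_cancer_risk:
- 0.0010040885926986555
- 0.002008177185397311
- 0.004016354370794622
- 0.010040885926986555
- 0.04016354370794622
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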
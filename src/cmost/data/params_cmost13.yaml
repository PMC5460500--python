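a0: 0.010580496161124721
a1: 0.13161919559725838
a2: 5.149625879595706
adenoma_risk_anchors_advanced:
  multipliers:
  - 0.003
  - 0.005
  - 0.08
  - 0.35
  - 0.9
  - 1.4
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
  - 0.5
  - 0.8
  - 1.2
  quantiles:
  - 0.0
  - 0.87
  - 0.92
  - 0.97
  - 1.0
b0: 0.4511536075710316
b1: 0.015848892118932784
b2: 1.7260222736182838
c0: 0.3649588852173092
c1: 0.013993894092912913
c2: 1.8961284418136315
direct_cancer_risk:
- 8.92822265625e-06
- 8.92822265625e-06
- 8.92822265625e-06
- 8.92822265625e-06
- 8.92822265625e-06
- 8.92822265625e-06
- 1.78564453125e-05
- 2.6784667968750004e-05
- 2.6784667968750004e-05
- 2.6784667968750004e-05
- 3.5712890625e-05
- 3.5712890625e-05
- 4.4641113281249996e-05
dwell_variant: 13
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
- 9.140778120348255
schema_version: 1
sex_factors:
- 1.352808548591109
- 1.1088043474904001
- 0.9639557936737742
sojourn_mean_y: 3.0
sojourn_sd_y: 0.5
stage_cancer_risk:
- 0.0010012234022252961
- 0.0020024468044505923
- 0.0040048936089011845
- 0.010012234022252962
- 0.04004893608901185
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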
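category,sex,age_lo,age_hi,value,weight,step
early_prev,A,40,40,0.12,1,I
early_prev,M,40,40,0.138,1,I
early_prev,F,40,40,0.102,1,I
early_prev,A,45,45,0.16,1,I
early_prev,M,45,45,0.184,1,I
early_prev,F,45,45,0.136,1,I
early_prev,A,50,50,0.21,1,I
early_prev,M,50,50,0.241,1,I
early_prev,F,50,50,0.178,1,I
early_prev,A,55,55,0.25,1,I
early_prev,M,55,55,0.287,1,I
early_prev,F,55,55,0.212,1,I
early_prev,A,60,60,0.29,1,I
early_prev,M,60,60,0.333,1,I
early_prev,F,60,60,0.246,1,I
early_prev,A,65,65,0.32,1,I
early_prev,M,65,65,0.368,1,I
early_prev,F,65,65,0.272,1,I
early_prev,A,70,70,0.34,1,I
early_prev,M,70,70,0.391,1,I
early_prev,F,70,70,0.289,1,I
early_prev,A,75,75,0.36,1,I
early_prev,M,75,75,0.414,1,I
early_prev,F,75,75,0.306,1,I
early_prev,A,80,80,0.37,1,I
early_prev,M,80,80,0.425,1,I
early_prev,F,80,80,0.315,1,I
adv_prev,A,40,40,0.008,1,II
adv_prev,M,40,40,0.0096,1,II
adv_prev,F,40,40,0.0064,1,II
adv_prev,A,45,45,0.012,1,II
adv_prev,M,45,45,0.0144,1,II
adv_prev,F,45,45,0.0096,1,II
adv_prev,A,50,50,0.022,1,II
adv_prev,M,50,50,0.0264,1,II
adv_prev,F,50,50,0.0176,1,II
adv_prev,A,55,55,0.03,1,II
adv_prev,M,55,55,0.036,1,II
adv_prev,F,55,55,0.024,1,II
adv_prev,A,60,60,0.04,1,II
adv_prev,M,60,60,0.048,1,II
adv_prev,F,60,60,0.032,1,II
adv_prev,A,65,65,0.05,1,II
adv_prev,M,65,65,0.06,1,II
adv_prev,F,65,65,0.04,1,II
adv_prev,A,70,70,0.062,1,II
adv_prev,M,70,70,0.0744,1,II
adv_prev,F,70,70,0.0496,1,II
adv_prev,A,75,75,0.072,1,II
adv_prev,M,75,75,0.0864,1,II
adv_prev,F,75,75,0.0576,1,II
adv_prev,A,80,80,0.082,1,II
adv_prev,M,80,80,0.0984,1,II
adv_prev,F,80,80,0.0656,1,II
crc_inc,A,45,49,33.0,1,III
crc_inc,M,45,49,39.6,1,III
crc_inc,F,45,49,27.4,1,III
crc_inc,A,50,54,60.0,1,III
crc_inc,M,50,54,72.0,1,III
crc_inc,F,50,54,49.8,1,III
crc_inc,A,55,59,85.0,1,III
crc_inc,M,55,59,102.0,1,III
crc_inc,F,55,59,70.5,1,III
crc_inc,A,60,64,115.0,1,III
crc_inc,M,60,64,138.0,1,III
crc_inc,F,60,64,95.4,1,III
crc_inc,A,65,69,155.0,1,III
crc_inc,M,65,69,186.0,1,III
crc_inc,F,65,69,128.7,1,III
crc_inc,A,70,74,200.0,1,III
crc_inc,M,70,74,240.0,1,III
crc_inc,F,70,74,166.0,1,III
crc_inc,A,75,79,245.0,1,III
crc_inc,M,75,79,294.0,1,III
crc_inc,F,75,79,203.3,1,III
crc_inc,A,80,84,285.0,1,III
crc_inc,M,80,84,342.0,1,III
crc_inc,F,80,84,236.5,1,III
crc_inc,A,85,89,300.0,1,III
crc_inc,M,85,89,360.0,1,III
crc_inc,F,85,89,249.0,1,III
crc_mort,A,50,54,17.0,1,III
crc_mort,A,55,59,25.0,1,III
crc_mort,A,60,64,37.0,1,III
crc_mort,A,65,69,53.0,1,III
crc_mort,A,70,74,75.0,1,III
crc_mort,A,75,79,105.0,1,III
crc_mort,A,80,84,145.0,1,III
crc_mort,A,85,89,180.0,1,III
rectum_share,A,50,69,0.29,1,III
rectum_share,A,70,85,0.27,1,III
mult2,A,60,60,0.35,1,I
mult2,A,70,70,0.38,1,I
mult3,A,60,60,0.15,1,I
synchronous,A,0,100,0.035,1,I
stage_sympt_1,A,0,100,0.12,1,III
stage_sympt_2,A,0,100,0.32,1,III
stage_sympt_3,A,0,100,0.31,1,III
stage_sympt_4,A,0,100,0.25,1,III
stage_screen_1,A,0,100,0.39,1,III
stage_screen_2,A,0,100,0.33,1,III
stage_screen_3,A,0,100,0.2,1,III
stage_screen_4,A,0,100,0.08,1,III
trial_inc_reduction,A,55,64,0.23,1,IV
trial_right_reduction,A,55,64,0.05,1,IV
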
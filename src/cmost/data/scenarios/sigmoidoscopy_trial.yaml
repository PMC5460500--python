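# one/two-time rectosigmoidoscopy trial arm (ITT), ages 55-74, 11.9y window
modality: sigmoidoscopy
enroll_age_range: [55, 74]
screen_offsets_y: [0, 4]
second_screen_fraction: 0.5
adherence: 0.835
followup_adherence: 0.72
followup_window_y: 11.9
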
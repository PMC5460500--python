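# screening colonoscopy every 10 years between ages 50 and 75
modality: colonoscopy
start_age: 50
stop_age: 75
interval_y: 10
adherence: 1.0
surveillance: true
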
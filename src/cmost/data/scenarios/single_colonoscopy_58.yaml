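# one lifetime screening colonoscopy at age 58
modality: colonoscopy
screen_ages: [58]
start_age: 58
stop_age: 59
adherence: 1.0
surveillance: true
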
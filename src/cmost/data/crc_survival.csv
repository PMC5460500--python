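stage,five_year_survival
1,0.93
2,0.82
3,0.63
4,0.10
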
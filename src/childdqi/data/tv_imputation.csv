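age_lo,age_hi,hours
2,6,2.0
7,14,4.0
15,18,3.5
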
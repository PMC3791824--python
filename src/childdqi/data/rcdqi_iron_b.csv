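age_lo,age_hi,ear_mg,rda_mg
2,3,3.0,7.0
4,8,4.1,10.0
9,13,5.7,8.0
14,18,7.9,15.0
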
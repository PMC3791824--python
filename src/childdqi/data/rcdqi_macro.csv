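component,kind,age_lo,age_hi,lo,hi,max_points
added_sugar,cap,2,18,,10,10
fat,range,2,3,30,40,2.5
fat,range,4,18,25,35,2.5
linoleic,range,2,18,5,10,2.5
linolenic,range,2,18,0.6,1.2,2.5
dha_epa,cap,2,18,,10,2.5
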
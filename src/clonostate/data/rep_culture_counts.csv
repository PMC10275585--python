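sample_id,day,gd_count_millions
CB12,0,0.05
CB12,7,7.7
CB12,14,969.408
CB12,21,49500
CB14,0,0.165
CB14,7,4.77
CB14,14,518.056
CB14,21,57820
CB26649,0,0.024
CB26649,7,25.558
CB26649,14,1302.444
CB26649,21,71703.429
CB39382,0,0.021
CB39382,7,15.055
CB39382,14,1219.504
CB39382,21,46666.667
CB39677,0,0.038
CB39677,7,36.495
CB39677,14,3227.85
CB39677,21,301968
CB40933,0,0.037
CB40933,7,9.296
CB40933,14,624.067
CB40933,21,21634.309
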
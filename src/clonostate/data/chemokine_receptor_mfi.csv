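sample_id,marker,day,mfi
CB1,CXCR3,0,58.2
CB1,CXCR3,21,436.3
CB9,CXCR3,0,44
CB9,CXCR3,21,578.2
CB8,CXCR3,0,50.2
CB8,CXCR3,21,431
CB1,CXCR6,0,0.2
CB1,CXCR6,21,576
CB9,CXCR6,0,4.6
CB9,CXCR6,21,828.1
CB8,CXCR6,0,0
CB8,CXCR6,21,422
CB1,CCR5,0,49.9
CB1,CCR5,21,24.2
CB9,CCR5,0,81.5
CB9,CCR5,21,82.1
CB8,CCR5,0,29.8
CB8,CCR5,21,32.3
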
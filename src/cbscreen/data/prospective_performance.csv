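model,n_tested,n_active,hit_rate
SB1,4,1,25
SB2,3,1,33.3
LB3,5,1,20
LB6,5,3,60
LB7,4,1,25
LB8,3,1,33.3
LB9,4,0,0
LB10,4,1,25
LB11,3,1,33.3
DS2,2,1,50
DS5,4,1,25
DS8,2,1,50
DS9,5,4,80
DS12,3,1,33.3
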
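model,specs,specs_np,phytchem
SB1,64,0,0
SB2,121,0,1
LB3,2624,0,0
LB4,0,0,0
LB5,3050,3,8
LB6,242,0,0
LB7,25,0,1
LB8,210,0,0
LB9,50,0,1
LB10,216,1,0
LB11,567,1,4
DS2,399,1,14
DS5,63,16,0
DS8,210,9,11
DS9,50,7,4
DS12,2961,2,4
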
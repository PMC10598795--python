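model,tp,fp,tn,fn,accuracy,sensitivity,specificity,yoa,ef
SB1,7,49,4852,88,0.97,0.07,0.99,0.13,6.57
SB2,6,69,4832,89,0.97,0.06,0.99,0.08,4.21
LB3,12,51,4850,83,0.97,0.13,0.99,0.19,10.02
LB4,8,15,4886,87,0.98,0.08,1.00,0.35,18.29
LB5,13,16,4885,82,0.98,0.14,1.00,0.45,23.57
LB6,5,24,4877,90,0.98,0.05,1.00,0.17,9.07
LB7,4,32,4869,91,0.98,0.04,0.99,0.11,5.84
LB8,3,18,4883,92,0.98,0.03,1.00,0.14,7.51
LB9,5,52,4849,90,0.97,0.05,0.99,0.09,4.61
LB10,5,58,4843,90,0.97,0.05,0.99,0.08,4.17
LB11,9,45,4856,86,0.97,0.09,0.99,0.17,8.76
DS2,10,49,4852,85,0.97,0.11,0.99,0.17,8.91
DS5,11,57,4844,84,0.97,0.12,0.99,0.16,8.51
DS8,10,74,4827,85,0.97,0.11,0.98,0.12,6.26
DS9,9,64,4837,86,0.97,0.09,0.99,0.12,6.48
DS12,15,86,4815,80,0.97,0.16,0.98,0.15,7.81
Combined,89,677,4224,6,0.86,0.94,0.86,0.12,6.11
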
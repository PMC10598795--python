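compound,concentration_um,inhibition_pct,sd
SC6,30,38.4,12.6
SC14,10,43.9,23.9
SC22,30,54.7,2.5
SC23,30,99.3,3.7
SC23,10,86.5,2.7
SC24,20,95.5,2.5
SC25,30,25.5,14.6
SC27,30,32.9,1.7
SC27,10,35.9,4.4
SC32,30,73.9,0.2
SC34,30,37.8,5.7
SC37,30,100.3,0.4
SC37,10,71.3,6.4
SC45,10,17.7,1.0
colchicine,30,98.8,5.2
colchicine,10,83.2,1.7
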
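geometry,O1,O2,O3,O4,O5,O6,O7,O8,O9,O10,O11,O12,O13,O14,O15,O16
HA,9.5,5.4,16.5,3.7,3.1,-,9.7,11.4,-,-,9.1,14,7.2,4.9,2.96,2.2
FPA,9.4,2.6,7.3,5.3,-,-,3.3,6.4,2.7,0.6,2.5,1.8,2.6,2.4,24.8,28.3
PTA,-,9.63,11.8,10.5,-,-,15.2,1.3,-,-,11.2,2.6,21.6,16.2,-,-
FTA,12.8,6.1,4.3,-,-,12.2,19.5,0.1,-,-,6.2,5.2,12.7,19,-,1.8
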
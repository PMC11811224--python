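brand,water_type,labeled,measured,sd
B1,DW,1.3,0.85,0.10
B2,MW,1.9,4.25,0.14
B3,MW,2,2.78,1.02
B4,DW,0.4,2.42,0.17
B5,MW,8,2.91,0.03
B6,DW,NL,4.28,0.03
B7,MW,1.1,2.81,0.01
B8,MW,0.74,0.18,0.01
B9,MW,4.5,1.91,0.01
B10,DW,< 2,2.17,0.03
B11,DW,9.5,3.89,0.06
B12,MW,< 0.8,1.75,0.01
B13,DW,< 1,0.02,0.01
B14,MW,2.45,0.53,0.01
B15,DW,2.56,4.96,0.04
B16,DW,< 10,0.56,0.07
B17,DW,0.61,1.04,0.04
B18,DW,6.8,1.33,0.01
B19,DW,NL,2.33,0.03
B20,DW,NL,2.20,0.01
B21,DW,7.22,3.63,0.04
B22,DW,5,2.91,0.03
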
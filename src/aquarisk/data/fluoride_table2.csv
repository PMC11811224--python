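brand,water_type,labeled,measured,sd
B1,DW,0.7,0.28,0.01
B2,MW,NL,0.30,0.01
B3,MW,NL,0.71,0.01
B4,DW,0.1,0.29,0.01
B5,MW,0.15,0.45,0.01
B6,DW,NL,0.49,0.03
B7,MW,0.09,0.20,0.00
B8,MW,0.414,0.35,0.01
B9,MW,NL,0.51,0.01
B10,DW,0.5,0.37,0.01
B11,DW,0.01,0.41,0.01
B12,MW,< 0.005,0.16,0.01
B13,DW,NL,0.22,0.00
B14,MW,0.1,0.11,0.01
B15,DW,0.25,0.70,0.02
B16,DW,< 1,0.01,0.01
B17,DW,0.07,0.11,0.03
B18,DW,0.05,0.36,0.00
B19,DW,NL,0.34,0.01
B20,DW,NL,0.16,0.02
B21,DW,0.22,0.24,0.24
B22,DW,NL,0.36,0.35
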
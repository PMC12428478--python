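code,X1,X2,X3,X4,X5,X6,X7,X8,X9,pmc_index
P1,0.67,0.33,0.33,0.67,1.00,0.60,1.00,1.00,1.00,6.60
P2,1.00,0.33,0.33,0.67,1.00,1.00,1.00,1.00,1.00,7.33
P3,0.83,0.33,0.33,0.67,1.00,1.00,1.00,0.80,0.60,6.57
P4,0.67,0.33,0.33,1.00,1.00,1.00,1.00,1.00,1.00,7.33
P5,0.83,0.33,0.33,0.67,0.80,0.80,1.00,1.00,0.60,6.37
P6,0.67,0.33,0.33,1.00,0.80,0.80,0.75,1.00,0.60,6.28
P7,0.67,0.33,0.33,1.00,1.00,1.00,1.00,1.00,1.00,7.33
P8,0.50,0.33,0.33,1.00,1.00,0.60,0.75,0.60,1.00,6.12
P9,1.00,0.33,0.33,1.00,1.00,1.00,1.00,1.00,0.80,7.47
P10,0.67,0.33,0.33,1.00,0.80,1.00,1.00,0.80,1.00,6.93
P11,0.50,0.33,0.33,0.33,0.60,0.80,0.75,0.80,0.60,5.05
P12,0.50,0.33,0.33,0.67,0.80,1.00,0.75,0.60,0.80,5.78
P13,0.33,0.33,0.33,0.67,0.40,0.60,1.00,0.80,0.40,4.87
P14,0.50,0.33,0.33,0.33,0.60,0.60,1.00,0.60,0.40,4.70
P15,0.50,0.33,0.33,0.33,0.40,0.60,1.00,0.80,0.40,4.70
P16,0.50,0.33,0.33,0.67,1.00,1.00,1.00,0.80,0.60,6.23
P17,0.50,0.33,1.00,1.00,0.80,1.00,1.00,0.80,0.40,6.83
P18,0.67,0.33,0.33,0.67,1.00,0.60,1.00,0.80,0.60,6.00
P19,0.67,0.33,0.33,0.67,1.00,1.00,1.00,1.00,0.80,6.80
P20,0.83,0.33,0.67,1.00,0.80,1.00,1.00,1.00,0.80,7.43
P21,0.67,0.33,0.33,1.00,1.00,1.00,1.00,0.80,0.80,6.93
P22,1.00,0.33,0.33,1.00,1.00,1.00,1.00,1.00,1.00,7.67
P23,0.67,0.33,0.33,0.67,0.60,0.80,1.00,0.80,0.80,6.00
P24,0.50,0.33,1.00,0.67,1.00,1.00,1.00,0.80,0.80,7.10
P25,1.00,0.33,0.33,1.00,1.00,1.00,1.00,1.00,0.80,7.47
P26,0.33,0.33,0.33,0.33,0.60,0.67,1.00,0.40,0.40,4.40
P27,0.83,0.33,0.67,1.00,1.00,0.80,1.00,1.00,0.80,7.43
P28,0.83,0.33,0.33,1.00,1.00,1.00,1.00,0.80,1.00,7.30
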
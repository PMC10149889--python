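measure,RTLS_Total,RTLS_Emotional,RTLS_Social,UCLA_8,UCLA_3,SI_Direct
RTLS_Total,1.00,0.86,0.84,0.71,0.65,0.66
RTLS_Emotional,0.86,1.00,0.46,0.63,0.69,0.66
RTLS_Social,0.84,0.46,1.00,0.58,0.42,0.45
UCLA_8,0.71,0.63,0.58,1.00,0.76,0.67
UCLA_3,0.65,0.69,0.42,0.76,1.00,0.66
SI_Direct,0.66,0.66,0.45,0.67,0.66,1.00
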
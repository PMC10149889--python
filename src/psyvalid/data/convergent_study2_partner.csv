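measure,RTLS_Total,RTLS_Emotional,RTLS_Social,UCLA_8,UCLA_3,SI_Direct
RTLS_Total,1.00,0.85,0.86,0.74,0.67,0.12
RTLS_Emotional,0.85,1.00,0.47,0.61,0.69,0.13
RTLS_Social,0.86,0.47,1.00,0.65,0.45,0.07
UCLA_8,0.74,0.61,0.65,1.00,0.74,0.15
UCLA_3,0.67,0.69,0.45,0.74,1.00,0.12
SI_Direct,0.12,0.13,0.07,0.15,0.12,1.00
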
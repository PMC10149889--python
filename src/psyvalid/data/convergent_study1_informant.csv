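measure,RTLS_Total,RTLS_Emotional,RTLS_Social,UCLA_20,UCLA_3,SI_Direct,SI_Indirect,SI_DirectFreq
RTLS_Total,1.00,0.95,0.89,0.85,0.76,0.67,0.68,0.43
RTLS_Emotional,0.95,1.00,0.72,0.80,0.75,0.72,0.70,0.44
RTLS_Social,0.89,0.72,1.00,0.77,0.65,0.49,0.53,0.34
UCLA_20,0.85,0.80,0.77,1.00,0.70,0.58,0.64,0.41
UCLA_3,0.76,0.75,0.65,0.70,1.00,0.61,0.65,0.39
SI_Direct,0.67,0.72,0.49,0.58,0.61,1.00,0.74,0.48
SI_Indirect,0.68,0.70,0.53,0.64,0.65,0.74,1.00,0.51
SI_DirectFreq,0.43,0.44,0.34,0.41,0.39,0.48,0.51,1.00
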
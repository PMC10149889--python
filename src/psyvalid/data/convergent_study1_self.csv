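measure,RTLS_Total,RTLS_Emotional,RTLS_Social,UCLA_20,UCLA_3,SI_Direct,SI_Indirect,SI_DirectFreq
RTLS_Total,1.00,0.93,0.89,0.87,0.73,0.61,0.62,0.66
RTLS_Emotional,0.93,1.00,0.66,0.77,0.75,0.66,0.64,0.71
RTLS_Social,0.89,0.66,1.00,0.82,0.57,0.43,0.47,0.46
UCLA_20,0.87,0.77,0.82,1.00,0.73,0.57,0.59,0.63
UCLA_3,0.73,0.75,0.57,0.73,1.00,0.59,0.56,0.66
SI_Direct,0.61,0.66,0.43,0.57,0.59,1.00,0.70,0.81
SI_Indirect,0.62,0.64,0.47,0.59,0.56,0.70,1.00,0.67
SI_DirectFreq,0.66,0.71,0.46,0.63,0.66,0.81,0.67,1.00
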
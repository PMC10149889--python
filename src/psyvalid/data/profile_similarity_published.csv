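measure_a,measure_b,icc_de,study
RTLS_Emotional,RTLS_Total,0.98,study1
RTLS_Social,RTLS_Total,0.97,study1
RTLS_Social,RTLS_Emotional,0.93,study1
UCLA_20,RTLS_Total,0.98,study1
UCLA_20,RTLS_Emotional,0.94,study1
UCLA_20,RTLS_Social,0.97,study1
UCLA_3,RTLS_Total,0.96,study1
UCLA_3,RTLS_Emotional,0.98,study1
UCLA_3,RTLS_Social,0.92,study1
UCLA_3,UCLA_20,0.93,study1
SI_Direct,RTLS_Total,0.88,study1
SI_Direct,RTLS_Emotional,0.94,study1
SI_Direct,RTLS_Social,0.84,study1
SI_Direct,UCLA_20,0.82,study1
SI_Direct,UCLA_3,0.93,study1
SI_Indirect,RTLS_Total,0.89,study1
SI_Indirect,RTLS_Emotional,0.94,study1
SI_Indirect,RTLS_Social,0.87,study1
SI_Indirect,UCLA_20,0.84,study1
SI_Indirect,UCLA_3,0.92,study1
SI_Indirect,SI_Direct,0.99,study1
SI_DirectFreq,RTLS_Total,0.87,study1
SI_DirectFreq,RTLS_Emotional,0.94,study1
SI_DirectFreq,RTLS_Social,0.82,study1
SI_DirectFreq,UCLA_20,0.80,study1
SI_DirectFreq,UCLA_3,0.93,study1
SI_DirectFreq,SI_Direct,0.99,study1
SI_DirectFreq,SI_Indirect,0.98,study1
RTLS_Emotional,RTLS_Total,0.97,study2
RTLS_Social,RTLS_Total,0.88,study2
RTLS_Social,RTLS_Emotional,0.77,study2
UCLA_8,RTLS_Total,0.96,study2
UCLA_8,RTLS_Emotional,0.91,study2
UCLA_8,RTLS_Social,0.90,study2
UCLA_3,RTLS_Total,0.95,study2
UCLA_3,RTLS_Emotional,0.98,study2
UCLA_3,RTLS_Social,0.79,study2
UCLA_3,UCLA_8,0.93,study2
SI_Direct,RTLS_Total,0.98,study2
SI_Direct,RTLS_Emotional,0.98,study2
SI_Direct,RTLS_Social,0.84,study2
SI_Direct,UCLA_8,0.95,study2
SI_Direct,UCLA_3,0.99,study2
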
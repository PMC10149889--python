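measure,informant_RTLS_Total,informant_RTLS_Emotional,informant_RTLS_Social,informant_UCLA_20,informant_UCLA_3,informant_SI_Direct,informant_SI_Indirect,informant_SI_DirectFreq
self_RTLS_Total,0.61,,,,,,,
self_RTLS_Emotional,0.56,0.57,,,,,,
self_RTLS_Social,0.58,0.56,0.52,,,,,
self_UCLA_20,0.59,0.57,0.51,0.61,,,,
self_UCLA_3,0.48,0.47,0.41,0.44,0.57,,,
self_SI_Direct,0.46,0.47,0.36,0.39,0.43,0.49,,
self_SI_Indirect,0.51,0.52,0.39,0.42,0.50,0.51,0.55,
self_SI_DirectFreq,0.43,0.44,0.34,0.41,0.39,0.48,0.51,0.53
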
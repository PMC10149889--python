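measure,partner_RTLS_Total,partner_RTLS_Emotional,partner_RTLS_Social,partner_UCLA_8,partner_UCLA_3,partner_SI_Direct
self_RTLS_Total,0.53,,,,,
self_RTLS_Emotional,0.47,0.49,,,,
self_RTLS_Social,0.43,0.32,0.42,,,
self_UCLA_8,0.48,0.42,0.41,0.55,,
self_UCLA_3,0.43,0.45,0.30,0.45,0.48,
self_SI_Direct,0.42,0.44,0.26,0.42,0.44,0.22
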
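correlate,domain,RTLS_Total,RTLS_Emotional,RTLS_Social,UCLA_8,UCLA_3,SI_Direct
Age,demography,-0.07,-0.15,0.04,-0.07,-0.15,-0.07
Gender,demography,-0.01,0.06,-0.09,0.05,0.17,0.12
Education,demography,-0.13,-0.10,-0.11,-0.01,-0.01,-0.04
RelationshipDuration,demography,-0.06,-0.10,0.01,-0.01,-0.06,-0.03
Neuroticism,personality,0.46,0.54,0.22,0.41,0.53,0.49
Extraversion,personality,-0.17,-0.09,-0.20,-0.30,-0.17,-0.15
Openness,personality,0.05,0.10,-0.02,0.04,0.07,0.08
Agreeableness,personality,-0.22,-0.14,-0.24,-0.27,-0.09,-0.16
Conscientiousness,personality,-0.20,-0.19,-0.15,-0.15,-0.18,-0.15
Shyness,personality,0.23,0.23,0.16,0.36,0.28,0.23
Sociability,personality,-0.14,-0.01,-0.24,-0.30,-0.05,-0.08
SelfEsteem,personality,-0.54,-0.55,-0.36,-0.48,-0.51,-0.52
AffiliationMotive,personality,-0.12,0.05,-0.26,-0.24,0.01,-0.05
Depressiveness,personality,0.56,0.60,0.33,0.55,0.58,0.58
SatLife,satisfaction,-0.39,-0.35,-0.30,-0.34,-0.27,-0.31
SatEducation,satisfaction,-0.31,-0.30,-0.21,-0.23,-0.23,-0.25
SatLeisure,satisfaction,-0.32,-0.29,-0.25,-0.33,-0.29,-0.30
SatFriends,satisfaction,-0.50,-0.39,-0.45,-0.48,-0.39,-0.42
SatFamily,satisfaction,-0.29,-0.25,-0.23,-0.23,-0.22,-0.24
SatPartner,satisfaction,-0.28,-0.27,-0.21,-0.24,-0.23,-0.29
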
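correlate,domain,RTLS_Total,RTLS_Emotional,RTLS_Social,UCLA_20,UCLA_3,SI_Direct,SI_Indirect,SI_DirectFreq
Age,demography,0.05,-0.03,0.13,0.08,-0.05,-0.09,0.00,-0.10
Gender,demography,-0.10,-0.04,-0.15,-0.15,-0.03,-0.04,-0.10,-0.03
Education,demography,-0.12,-0.10,-0.11,-0.11,-0.06,-0.11,-0.10,-0.11
Partnered,demography,-0.19,-0.21,-0.13,-0.18,-0.10,-0.25,-0.24,-0.23
Neuroticism,personality,0.29,0.34,0.18,0.24,0.37,0.21,0.19,0.26
Extraversion,personality,-0.34,-0.30,-0.33,-0.46,-0.33,-0.19,-0.20,-0.20
Openness,personality,-0.15,-0.08,-0.20,-0.20,-0.11,-0.07,-0.07,-0.03
Agreeableness,personality,-0.23,-0.17,-0.27,-0.29,-0.16,-0.10,-0.13,-0.08
Conscientiousness,personality,-0.21,-0.18,-0.21,-0.22,-0.17,-0.18,-0.15,-0.16
Shyness,personality,0.34,0.33,0.28,0.39,0.39,0.25,0.24,0.27
Sociability,personality,-0.30,-0.19,-0.37,-0.42,-0.20,-0.06,-0.13,-0.06
SelfEsteem,personality,-0.53,-0.53,-0.42,-0.49,-0.53,-0.47,-0.46,-0.50
AffiliationMotive,personality,-0.25,-0.11,-0.36,-0.40,-0.09,-0.04,-0.11,-0.00
UnsatisfiedNeeds,personality,0.57,0.49,0.48,0.57,0.55,0.38,0.33,0.37
FrustratedAffiliation,personality,-0.06,-0.01,-0.10,-0.10,-0.01,-0.06,-0.07,0.00
Depressiveness,personality,0.62,0.61,0.52,0.64,0.58,0.49,0.48,0.56
SocialDesirability,personality,-0.05,-0.05,-0.05,-0.04,-0.05,-0.03,-0.01,-0.02
SatLife,satisfaction,-0.53,-0.51,-0.45,-0.53,-0.43,-0.49,-0.53,-0.49
SatEducation,satisfaction,-0.36,-0.34,-0.32,-0.36,-0.33,-0.32,-0.30,-0.33
SatLeisure,satisfaction,-0.45,-0.41,-0.40,-0.48,-0.38,-0.38,-0.40,-0.35
SatFriends,satisfaction,-0.66,-0.64,-0.55,-0.64,-0.60,-0.47,-0.47,-0.43
SatFamily,satisfaction,-0.42,-0.37,-0.41,-0.44,-0.37,-0.39,-0.35,-0.35
SatPartner,satisfaction,-0.34,-0.36,-0.26,-0.32,-0.21,-0.33,-0.34,-0.30
FriendsOverall,network,-0.32,-0.25,-0.35,-0.36,-0.24,-0.16,-0.17,-0.16
FriendsFacebook,network,-0.04,-0.01,-0.07,-0.08,-0.03,-0.05,-0.05,-0.03
HelpProblems,network,-0.38,-0.29,-0.42,-0.37,-0.23,-0.19,-0.20,-0.17
InstrumentalSupport,network,-0.37,-0.31,-0.36,-0.35,-0.27,-0.22,-0.26,-0.21
Advice,network,-0.22,-0.18,-0.23,-0.24,-0.16,-0.17,-0.19,-0.19
ContactFrequency,network,-0.22,-0.15,-0.27,-0.27,-0.13,-0.02,-0.08,-0.02
JointActivities,network,-0.41,-0.34,-0.42,-0.45,-0.31,-0.17,-0.15,-0.12
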
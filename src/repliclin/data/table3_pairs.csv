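pair_id,measure,orig_point,orig_lo,orig_hi,rep_point,rep_lo,rep_hi,direction,original_significant,order_inverted,original_design,intervention_type,citations_per_year,original_n,original_p
Brahmer2012,ORR,0.13,0.06,0.17,0.27,0.21,0.33,favorable,not_applicable,false,phase1,pharmacological,,,
Topalian2012,ORR,0.21,0.16,0.26,0.26,0.21,0.31,favorable,not_applicable,false,phase1,pharmacological,,,
TAXUS-IV,RR,0.39,0.26,0.59,0.66,0.59,0.74,unfavorable,significant,false,RCT,nonpharmacological,,,
SYNTAX,OR,1.44,1.11,1.89,1.42,1.27,1.59,unfavorable,significant,false,RCT,nonpharmacological,,,
HERA,HR,0.54,0.43,0.67,0.65,0.55,0.75,unfavorable,significant,false,RCT,pharmacological,,,
CATIE,HR,0.63,0.52,0.76,0.68,0.56,0.83,unfavorable,significant,false,RCT,pharmacological,,,
SHARP,HR,0.69,0.55,0.87,0.69,0.60,0.79,unfavorable,significant,false,RCT,pharmacological,,,
ERSPC,IRR,0.80,0.65,0.98,0.96,0.85,1.08,unfavorable,significant,false,RCT,nonpharmacological,,,
PROFILE-1007,HR,0.49,0.37,0.64,0.46,0.39,0.54,unfavorable,significant,false,RCT,pharmacological,,,
ACCORD,RR,0.95,0.82,1.09,0.92,0.85,1.00,unfavorable,nonsignificant,false,RCT,pharmacological,,,
Cheng2009,HR,0.68,0.50,0.93,0.69,0.60,0.79,unfavorable,significant,true,RCT,pharmacological,,,
EXTEND-IA,OR,6,2,18,4.04,2.75,5.93,favorable,significant,false,RCT,nonpharmacological,,,
PARTNER-A,RR,0.98,0.75,1.26,0.73,0.54,0.98,unfavorable,nonsignificant,false,RCT,nonpharmacological,,,
MR-CLEAN,RR,1.73,1.27,2.35,1.37,1.14,1.64,favorable,significant,false,RCT,nonpharmacological,,,
ECASS-III,OR,1.34,1.02,1.76,1.29,1.16,1.43,favorable,significant,false,RCT,nonpharmacological,,,
EURTAC,HR,0.37,0.25,0.54,0.23,0.17,0.30,unfavorable,significant,true,RCT,pharmacological,,,
ESCAPE,RR,1.86,1.39,2.47,1.37,1.14,1.64,favorable,significant,true,RCT,nonpharmacological,,,
NEJSG,HR,0.32,0.22,0.41,0.48,0.36,0.64,unfavorable,significant,true,RCT,pharmacological,,,
Hamid2013,ORR,0.38,0.25,0.44,0.29,0.26,0.32,favorable,not_applicable,false,phase1,pharmacological,,,
KEYNOTE-024,HR,0.50,0.37,0.68,1.07,0.94,1.21,unfavorable,significant,false,RCT,pharmacological,,,
KEYNOTE-001,ORR,0.19,0.16,0.23,0.25,0.22,0.29,favorable,not_applicable,false,phase1,pharmacological,,,
Wolchock2013,ORR,0.40,0.27,0.55,0.44,0.38,0.49,favorable,not_applicable,false,phase1,pharmacological,,,
Flaherty2010,ORR,0.81,0.63,0.93,0.48,0.42,0.55,favorable,not_applicable,false,phase1,pharmacological,,,
Fong2009,ORR,0.47,0.24,0.71,0.26,0.21,0.32,favorable,not_applicable,false,phase1,pharmacological,,,
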
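patient_id,age_years,sex,matched_control,onset_type,alsfrs_total,kings_stage,pumns
P1,50,F,yes,UL,44,1,1
P2,74,F,yes,LL,25,3,22
P3,36,M,yes,LL,45,1,15
P4,48,M,yes,UL,37,2,2
P5,53,M,yes,B,33,3,2
P6,66,M,yes,UL,41,2,3
P7,60,M,yes,UL,40,1,11
P8,52,F,yes,UL,42,2,16
P9,64,F,yes,B,47,1,1
P10,77,F,yes,UL,35,1,0
P11,72,F,yes,B,46,1,1
P12,73,M,yes,UL,34,2,9
P13,25,M,no,UL,33,3,7
P14,35,M,no,LL,17,3,12
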
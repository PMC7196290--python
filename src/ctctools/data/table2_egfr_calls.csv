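# ctctools-schema: mutation_calls v1
sample_id,patient_id,stage,locus,tissue_call,ctc_call,sex,age,tnm_stage
LP1,LP1,,L858R,+,+,F,52,IV
LP1,LP1,,T790M,-,-,F,52,IV
LP5,LP5,,L858R,+,+,M,49,IV
LP5,LP5,,T790M,-,-,M,49,IV
LP6,LP6,,L858R,+,+,M,58,IV
LP6,LP6,,T790M,-,-,M,58,IV
LP8,LP8,,L858R,+,+,F,76,IV
LP8,LP8,,T790M,-,-,F,76,IV
LP10,LP10,,L858R,+,+,M,63,IV
LP10,LP10,,T790M,-,-,M,63,IV
LP12,LP12,,L858R,+,+,F,90,IV
LP12,LP12,,T790M,-,-,F,90,IV
LP13,LP13,,L858R,+,+,F,53,IV
LP13,LP13,,T790M,-,-,F,53,IV
LP46,LP46,,L858R,+,+,F,67,IV
LP46,LP46,,T790M,-,-,F,67,IV
LP47,LP47,,L858R,+,+,F,83,IV
LP47,LP47,,T790M,-,-,F,83,IV
LP49-BT,LP49,BT,L858R,+,+,F,65,IIIA
LP49-BT,LP49,BT,T790M,-,-,F,65,IIIA
LP49-AR,LP49,AR,L858R,+,+,F,65,IIIA
LP49-AR,LP49,AR,T790M,+,+,F,65,IIIA
LP2-BT,LP2,BT,19del,+,+,M,53,IV
LP2-BT,LP2,BT,T790M,-,-,M,53,IV
LP2-AR,LP2,AR,19del,+,+,M,53,IV
LP2-AR,LP2,AR,T790M,+,+,M,53,IV
LP25,LP25,,19del,+,+,M,74,IV
LP25,LP25,,T790M,-,-,M,74,IV
LP43,LP43,,19del,+,+,F,59,IV
LP43,LP43,,T790M,-,-,F,59,IV
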
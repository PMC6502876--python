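name	forward_seq	reverse_seq	region	printed_length	target_group	gene	hits
amoA1f-amoA2r					AOB	amoA
Amx809f-Amx1066r					AnAOB	16S
Amx368f-Amx820r					AnAOB	16S
hzsA526F/hzsA1829R					AnAOB	hzs
hzsA1597F/hzsA1857R					AnAOB	hzs
Nitro1198f-Nitro1423r					Nitrospira	16S
NSR1113f-NSR1264r					Nitrospira	16S
NTSPAf-NTSPAr					Nitrobacter	16S
nirScd3af-nirSR3cd					DNB	nirS
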
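name	forward_seq	reverse_seq	region	printed_length	target_group	gene	hits
338f-518r			V3-V4	180	EUB	16S	6
341f-543r			V3-V4	202	EUB	16S	4
341f-907r			V3-V5	566	EUB	16S	2
519f-907r			V4-V5	391	EUB	16S	2
515f-806r			V4-V5	291	EUB	16S	1
907f-1110r			V6-V7	203	EUB	16S	1
1055f-1392r			V7-V8	337	EUB	16S	12
1369f-1492r			V8-V9	123	EUB	16S	3
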
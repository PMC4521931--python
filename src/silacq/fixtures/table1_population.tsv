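dataset	mean_log2	sd_log2	up_95	down_95	up_99	down_99	up_999	down_999
KK47_ML	-0.072	1.237	36	74	13	22	7	3
YTS1_HL	-0.151	1.143	17	70	6	27	1	3
both			2	33	2	3	0	0
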
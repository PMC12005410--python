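target_id	position	base	count
6S1_pRNA	5	G	1
6S1_pRNA	6	G	9
6S1_pRNA	7	T	903
6S1_pRNA	9	A	2422
6S1_pRNA	10	A	1491
6S1_pRNA	11	A	926
6S1_pRNA	12	A	899
6S1_pRNA	14	T	647
6S1_pRNA	15	A	13
6S1_pRNA	16	G	2
6S1_pRNA	18	T	1
6S1_pRNA	19	G	6
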
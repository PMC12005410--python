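target_id	position	base	count
6S1_pRNA	6	G	3
6S1_pRNA	7	T	200
6S1_pRNA	9	A	497
6S1_pRNA	10	A	368
6S1_pRNA	11	A	253
6S1_pRNA	12	A	98
6S1_pRNA	14	T	109
6S1_pRNA	15	A	2
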
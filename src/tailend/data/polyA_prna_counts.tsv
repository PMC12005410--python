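target_id	position	base	count
6S1_pRNA	5	G	4
6S1_pRNA	6	G	2
6S1_pRNA	7	T	4
6S1_pRNA	8	C	488
6S1_pRNA	13	C	48
6S1_pRNA	14	T	35
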
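target_id	position	base	count
tRNA_Glu_3p_synthetic	72	G	57
tRNA_Glu_3p_synthetic	74	C	1
tRNA_Glu_3p_synthetic	75	C	21
tRNA_Glu_3p_synthetic	76	A	133
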
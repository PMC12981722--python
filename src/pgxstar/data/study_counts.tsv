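gene	allele	haplotype_count
CYP2D6	*1	92
CYP2D6	*2	63
CYP2D6	*4	28
CYP2D6	*5	4
CYP2D6	*6	1
CYP2D6	*9	2
CYP2D6	*10	27
CYP2D6	*33	1
CYP2D6	*35	6
CYP2D6	*41	16
CYP2D6	*59	1
CYP2D6	*71	27
CYP2D6	*108	1
CYP2D6	*1x2	1
CYP2C19	*1	89
CYP2C19	*2	44
CYP2C19	*3	1
CYP2C19	*17	12
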
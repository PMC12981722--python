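gene	allele	suballele	function	activity_score	structural	grch38_positions	variants
#reference	NG_008384.3
CYP2C19	*1	.	normal	.	none	.	.
CYP2C19	*2	.	no_function	.	none	.	24179:G>A:rs4244285
CYP2C19	*3	.	no_function	.	none	.	22906:G>A:rs4986893:W212X
CYP2C19	*17	.	increased	.	none	.	4220:C>T:rs12248560
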
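gene	allele	suballele	function	activity_score	structural	grch38_positions	variants
#reference	NG_008376.4
CYP2D6	*1	.	normal	1	none	.	.
CYP2D6	*1	*1.069	normal	.	none	42130568	5243:C>T:rs1208092320
CYP2D6	*1	*1.070	normal	.	none	42131137	4674:T>C
CYP2D6	*1	*1.071	normal	.	none	42128779	7032:G>A:rs752453767
CYP2D6	*2	.	normal	1	none	42127941;42126611	7870:C>T:rs16947:R296C;9200:G>C:rs1135840:S486T
CYP2D6	*2	*2.038	normal	.	none	42128546	7265:C>T:rs936306239
CYP2D6	*2	*2.039	normal	.	none	42129001	6810:A>G:rs76326664
CYP2D6	*4	.	no_function	0	none	42130692;42128945	5119:C>T:rs1065852:P34S;6866:G>A:rs3892097
CYP2D6	*4	*4.036	no_function	.	none	42130709	5102:G>A:rs377617003:R28H
CYP2D6	*4	*4.037	no_function	.	none	42127383	8428:T>C:rs28371728
CYP2D6	*4	*4.038	no_function	.	none	42127365	8446:C>G:rs1483955943
CYP2D6	*5	.	no_function	0	deletion	.	.
CYP2D6	*6	.	no_function	0	none	42128242	7569:CT>C:rs5030655
CYP2D6	*9	.	decreased	0.5	none	42127986	7825:GAAG>G:rs5030656:K281del
CYP2D6	*10	.	decreased	0.25	none	42130692	5119:C>T:rs1065852:P34S
CYP2D6	*33	.	normal	1	none	42128159	7652:C>A:rs28371717:A237S
CYP2D6	*35	.	normal	1	none	42130761	5050:G>A:rs769258:V11M
CYP2D6	*41	.	decreased	0.5	none	42127803	8008:G>A:rs28371725
CYP2D6	*41	*41.010	decreased	.	none	42128438	7373:G>A:rs79650744
CYP2D6	*59	.	decreased	0.5	none	42127831	7980:G>A:rs79292917
CYP2D6	*71	.	uncertain	.	none	42130667	5144:G>A:rs118203758:G42E
CYP2D6	*108	.	unknown	.	none	42127406	8405:A>G:rs202102799:Y355C
CYP2D6	*186	.	unknown	.	none	42129105	6706:G>T:rs1399114415:G145C
CYP2D6	*186	*186.001	unknown	.	none	.	.
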
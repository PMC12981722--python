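gene	population	allele	freq	n_individuals
CYP2D6	oceanian	*1	0.617	999
CYP2D6	oceanian	*2	0.061	999
CYP2D6	oceanian	*4	0.018	999
CYP2D6	oceanian	*5	0.035	999
CYP2D6	oceanian	*6	0	999
CYP2D6	oceanian	*9	0	999
CYP2D6	oceanian	*10	0.057	999
CYP2D6	oceanian	*33	n.d.	999
CYP2D6	oceanian	*35	0.004	999
CYP2D6	oceanian	*41	0.032	999
CYP2D6	oceanian	*59	0.002	999
CYP2D6	oceanian	*71	0.043	999
CYP2D6	oceanian	*108	n.d.	999
CYP2D6	oceanian	*1x2	0.119	999
CYP2D6	european	*1	0.285	65090
CYP2D6	european	*2	0.185	65090
CYP2D6	european	*4	0.185	65090
CYP2D6	european	*5	0.03	65090
CYP2D6	european	*6	0.011	65090
CYP2D6	european	*9	0.028	65090
CYP2D6	european	*10	0.016	65090
CYP2D6	european	*33	0.01	65090
CYP2D6	european	*35	0.055	65090
CYP2D6	european	*41	0.092	65090
CYP2D6	european	*59	0	65090
CYP2D6	european	*71	0	65090
CYP2D6	european	*108	0.003	65090
CYP2D6	european	*1x2	0.008	65090
CYP2C19	oceanian	*1	0.625	999
CYP2C19	oceanian	*2	0.147	999
CYP2C19	oceanian	*3	0.002	999
CYP2C19	oceanian	*17	0.215	999
CYP2C19	european	*1	0.187	65090
CYP2C19	european	*2	0.610	65090
CYP2C19	european	*3	0.146	65090
CYP2C19	european	*17	0.057	65090
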
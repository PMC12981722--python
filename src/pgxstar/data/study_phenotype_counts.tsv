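gene	phenotype	count
CYP2D6	ultra_rapid	1
CYP2D6	normal	73
CYP2D6	intermediate	34
CYP2D6	poor	1
CYP2D6	uncertain	26
CYP2C19	ultra_rapid	0
CYP2C19	rapid	7
CYP2C19	normal	27
CYP2C19	intermediate	33
CYP2C19	poor	6
CYP2C19	uncertain	0
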
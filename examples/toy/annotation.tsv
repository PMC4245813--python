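category	name	start	end
domain	POU_S	1	70
domain	POU_HD	75	137
helix	POU_S_h1	8	20
helix	POU_S_h3	40	48
helix	POU_HD_h3	118	134
contact	pos60	60	60
contact	pos91	91	91
dipeptide	final	136	137
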
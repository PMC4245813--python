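# pou-trajectory structural annotation fixture for the POU_S + POU_HD column space
# 1-based inclusive columns; categories: domain, helix, contact, dipeptide.
# DNA-contact positions 60, 64, 91 and 134 are the text-named binding sites;
# helix intervals are plausible alpha-helix spans of the two subdomains and
# are meant to be overridden by a user-supplied annotation when available.
category	name	start	end
domain	POU_S	1	75
domain	POU_HD	78	137
helix	POU_S_h1	8	20
helix	POU_S_h2	26	34
helix	POU_S_h3	40	48
helix	POU_S_h4	55	71
helix	POU_HD_h1	87	98
helix	POU_HD_h2	104	112
helix	POU_HD_h3	118	134
contact	pos46	46	46
contact	pos49	49	49
contact	pos57	57	57
contact	pos60	60	60
contact	pos64	64	64
contact	pos88	88	88
contact	pos91	91	91
contact	pos125	125	128
contact	pos131	131	131
contact	pos134	134	134
dipeptide	final	136	137
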
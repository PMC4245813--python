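leaf	species
Amphimedon_g1	Amphimedon
Amphimedon_g2	Amphimedon
Nematostella_g3	Nematostella
Amphimedon_g4	Amphimedon
Nematostella_g5	Nematostella
Drosophila_g6	Drosophila
Danio_g7	Danio
Homo_g8	Homo
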
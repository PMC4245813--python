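(((((Amphimedon_g1:0.6071876935,Amphimedon_g2:0.6071876935)g5:0.3928123065,Nematostella_g3:1)g4:0.8536265737,(Amphimedon_g4:1,Nematostella_g5:1)g6:0.8536265737)g3:0.1463734263,Drosophila_g6:2)g2:1,(Danio_g7:2,Homo_g8:2)g7:1)g1;
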
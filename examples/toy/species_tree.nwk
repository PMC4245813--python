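(((Amphimedon:1,Nematostella:1):1,Drosophila:2):1,(Danio:2,Homo:2):1);
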
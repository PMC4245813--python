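alignment: examples/toy/alignment.fasta
gene_tree: examples/toy/gene_tree.nwk
species_tree: examples/toy/species_tree.nwk
species_map: examples/toy/species_map.tsv
annotation: examples/toy/annotation.tsv
model: LG
gamma_k: 4
alpha: auto
rooting: dl
families:
  paralogA:
  - Amphimedon_g1
  - Amphimedon_g2
  - Nematostella_g3
  paralogB:
  - Amphimedon_g4
  - Nematostella_g5
out_dir: toy_out
seed: 0
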
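# Demo pipeline configuration: a synthetic 7 kb circular plasmid carrying
# a 1 kb gene ("bla") whose transcribed strand is repaired 2.5x faster in
# the mfd+ library, and an unenriched control gene ("mPer1").
reference: examples/demo_plasmid.fa
genes: examples/demo_genes.bed
mode: prokaryote
topology: circular
n_molecules: 20000
e_plus:
  bla: 2.5
e_minus: {}
subsample_n: 200000
seed: 20230916
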
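# Demo pipeline configuration: a compact five-genotype synthetic panel
# (~200 genes per chromosome, 3 replicates) that exercises every stage.
outdir: demo_out
seed: 5
euploid: euploid
contrasts:
  - [M4B, euploid]
  - [Tri4B, euploid]
  - [SegT2A, euploid]
  - [N7B+SegT2A, SegT2A]
fpkm_filter: 1.0
fdr: 0.05
loess_span: 0.1
simulate:
  genes_per_chromosome: 200
  replicates_per_genotype: 3
  seed: 5
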
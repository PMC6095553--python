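# Full-pipeline profile: generate a 60 kb synthetic mitogenome carrying
# planted repeats, pseudogene fragments, genes and introns, then run every
# analysis stage on it. Outputs are byte-reproducible for a given seed.
seed: 1
synthetic:
  length: 60000
outdir: mitocomp_bundle
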
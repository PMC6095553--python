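trait	value
genome_bp	484916
gc_percent	45.4
gene_bp	64347
protein_exon_bp	29501
intron_bp	28035
intergenic_bp	420569
repeat_bp	19601
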
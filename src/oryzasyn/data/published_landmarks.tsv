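name	value
cg14_contig_kb	813
cg14_bac_total_kb	1102
cg14_gene_count	143
nipponbare_chr6_start	1900806
nipponbare_chr6_end	2748457
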
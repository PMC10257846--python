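chrom	start	end	name	analysis	merge_group
chr2	33000000	33500000	ctrl_chr2	1
chr5	98000000	98500000	ctrl_chr5	0
chr9	27000000	27500000	ctrl_chr9	1
chr14	61000000	61500000	ctrl_chr14	1
chr17	30000000	30500000	ctrl_chr17a	1	chr17
chr17	31500000	32000000	ctrl_chr17b	1	chr17
chr20	18000000	18500000	ctrl_chr20	0
chrX	96000000	96500000	ctrl_chrX	0
chrY	14000000	14500000	ctrl_chrY	0
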
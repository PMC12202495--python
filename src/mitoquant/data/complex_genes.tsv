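gene	fold_change_printed	fdr	tpm_a	tpm_b	gene_name
MT-ND1	19.21	5.19e-67	21.03	399.34	NADH:ubiquinone oxidoreductase core subunit 1
NDUFA9	9.98	1.88e-29	0.46	4.60	NADH:ubiquinone oxidoreductase core subunit A9
NDUFS1	-2.59	3.24e-11	38.09	14.64	NADH:ubiquinone oxidoreductase core subunit S1
NDUFA4L2	2.03	0.49	0.35	0.69	NADH:ubiquinone oxidoreductase core subunit A4L2
SDHA	1.96	0.0004	9.51	18.56	Succinate dehydrogenase subunit A
SDHB	-1.52	0.00018	178.70	117.18	Succinate dehydrogenase subunit B
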
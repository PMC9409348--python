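reference_sequence	start	end	variants	nearest_gene	short_name	in_gene
CACTIG010000023.1	35214339	35219825	46	NC_048332.1|vascular_cell_adhesion_molecule_1b	vcam1b	+
CACTIG010000039.1	31510109	31517637	52	NC_048333.1|sorting_nexin-7-like	snx7	-
CACTIG010000069.1	54920692	54925300	30	NC_048323.1|sorting_nexin-25-like	snx25	+
CACTIG010000082.1	11280103	11289542	32	NC_048336.1|decorin-like	dcn	-
CACTIG010000082.1	27990061	27998319	47	NC_048336.1|dnaJ_homolog_subfamily_B_member_9-like	dnajb9	-
CACTIG010000152.1	22143064	22149608	86	NC_048348.1|potassium_voltage-gated_channel_subfamily_C_member_1	kcnc1	+
CACTIG010000179.1	61245978	61249200	32	NC_048326.1|orofacial_cleft_1_candidate_gene_1_protein_homolog	ofcc1	+
CACTIG010000194.1	91630461	91639996	34	NC_048325.1|neuropilin_and_tolloid-like_protein_1	neto1	-
CACTIG010000208.1	13330045	13338213	34	NC_048342.1|neuronal_migration_protein_doublecortin-like	dcx	-
CACTIG010000217.1	58035319	58039159	39	NC_048327.1|phosphatase_and_actin_regulator_2-like	phactr2	+
CACTIG010000217.1	58052280	58058468	42	NC_048327.1|phosphatase_and_actin_regulator_2-like	phactr2	+
CACTIG010000236.1	7300133	7309147	31	NC_048329.1|protein_mono-ADP-ribosyltransferase_PARP12-like	parp12	+
CACTIG010000236.1	11730268	11739819	37	NC_048329.1|SH3_and_multiple_ankyrin_repeat_domains_3a	shank3a	+
CACTIG010000236.1	12145816	12147030	30	NC_048329.1|protein_FAM107B-like	fam107b	-
CACTIG010000236.1	45581476	45589775	53	NC_048329.1|synaptic_vesicular_amine_transporter-like	slc18	+
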
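srna_id	start	end	strand	length	upstream_gene	downstream_gene	orientation
IGR-113	337052	337338	+	286	Signal recognition particle protein	cysteinyl-tRNA synthetase	→→←
IGR-130	406166	406479	+	313	Hypothetical protein Balac_0325	ribonucleoside-diphosphate reductase subunit beta	→→←
IGR-136	426611	426713	+	102	Response regulator of two-component system	Phosphate-binding transport protein of ABC transporter system	→→→
IGR-2	5224	5584	+	360	Hypothetical protein BLA_0004	DNA gyrase subunit B	→→→
IGR-217	707356	707488	+	132	Hypothetical protein	Nucleotidyltransferase/DNA polymerase involved in DNA repair	←→→
IGR-33	87444	87318	-	126	Integral membrane protein	N6-adenine-specific methylase	→←→
IGR-36	96352	96163	-	189	Serine/threonine-protein kinase PknB	Serine-threonine protein kinase	←←→
IGR-392	1506611	1506740	+	129	ATP-dependent helicase	Putative CRISPR-associated Csb2 family protein	←→←
IGR-466	1779897	1780115	+	218	16s_rRNA	UDP-galactopyranose mutase	←→←
IGR-64	183658	183850	+	192	Amino acid permease	ABC transporter ATP-binding protein	→→→
IGR-93	286390	286859	+	469	phosphohydrolase	IclR-type transcriptional regulator	→→←
IGR-136	426611	426713	+	102	Response regulator of two-component system	Phosphate-binding transport protein of ABC transporter system	→→→
IGR-2	5224	5584	+	360	Hypothetical protein BLA_0004	DNA gyrase subunit B	→→→
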
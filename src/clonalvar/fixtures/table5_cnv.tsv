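strain	start	end	size_text	loci	products
A	341278	349235	7.96 kb	X276_25195;X276_25190;X276_25185;X276_25180;X276_25175;X276_25170;X276_25165;X276_25160;X276_25155;X276_25150;X276_25145	DNA-3-methyladenine glycosylase 2 family protein;Site-specific integrase;XRE family transcriptional regulator;Hypothetical protein;Transcription factor;Hypothetical protein;Replication protein;Hypothetical protein;Hypothetical protein;Hypothetical protein;Hypothetical protein
B	341243	349259	8.02 kb	X276_25195;X276_25190;X276_25185;X276_25180;X276_25175;X276_25170;X276_25165;X276_25160;X276_25155;X276_25150;X276_25145	DNA-3-methyladenine glycosylase 2 family protein;Site-specific integrase;XRE family transcriptional regulator;Hypothetical protein;Transcription factor;Hypothetical protein;Replication protein;Hypothetical protein;Hypothetical protein;Hypothetical protein;Hypothetical protein
C	341297	349217	7.92 kb	X276_25195;X276_25190;X276_25185;X276_25180;X276_25175;X276_25170;X276_25165;X276_25160;X276_25155;X276_25150;X276_25145	DNA-3-methyladenine glycosylase 2 family protein;Site-specific integrase;XRE family transcriptional regulator;Hypothetical protein;Transcription factor;Hypothetical protein;Replication protein;Hypothetical protein;Hypothetical protein;Hypothetical protein;Hypothetical protein
B33	167230	167409	180 bp	X276_26025	PIN/TRAM domain-containing protein
B33	499439	499573	135 bp		Only intergenic
B33	575045	575230	186 bp		Only intergenic
B33	728816	728957	142 bp	X276_23400	Hypothetical protein
B33	6042705	6042895	191 bp	X276_00695	Methyl-accepting chemotaxis protein
B33	6137871	6138337	467 bp	X276_00305	23S rRNA [pseudouridine(1915)-N(3)]-methyltransferase RlmH
B44	341237	349270	8.03 kb	X276_25195;X276_25190;X276_25185;X276_25180;X276_25175;X276_25170;X276_25165;X276_25160;X276_25155;X276_25150;X276_25145	DNA-3-methyladenine glycosylase 2 family protein;Site-specific integrase;XRE family transcriptional regulator;Hypothetical protein;Transcription factor;Hypothetical protein;Replication protein;Hypothetical protein;Hypothetical protein;Hypothetical protein;Hypothetical protein
E15	4901	5166	266 bp	X276_26795	DNA topoisomerase (ATP-hydrolyzing) subunit B
E28	341278	349256	7.98 kb	X276_25195;X276_25190;X276_25185;X276_25180;X276_25175;X276_25170;X276_25165;X276_25160;X276_25155;X276_25150;X276_25145	DNA-3-methyladenine glycosylase 2 family protein;Site-specific integrase;XRE family transcriptional regulator;Hypothetical protein;Transcription factor;Hypothetical protein;Replication protein;Hypothetical protein;Hypothetical protein;Hypothetical protein;Hypothetical protein
E33	341393	349134	7.74 kb	X276_25190;X276_25185;X276_25180;X276_25175;X276_25170;X276_25165;X276_25160;X276_25155;X276_25150;X276_25145	Site-specific integrase;XRE family transcriptional regulator;Hypothetical protein;Transcription factor;Hypothetical protein;Replication protein;Hypothetical protein;Hypothetical protein;Hypothetical protein;Hypothetical protein
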
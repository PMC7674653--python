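strain	position	ref	alt	locus	product	start	end	strand	feature	aa_ref	aa_alt
A	863781	T	G	X276_22865	Carbohydrate ABC transporter permease	863698	864525	+		I	M
A	1661343	C	T	X276_19395	Peptidase S8 and S53 subtilisin kexin sedolisin	1661151	1662989	+		L	F
A	2775912	T	C	X276_14460	Cytochrome b5	2775169	2775996	+		T	T
A	3007463	C	A	X276_13415	S-layer family protein	3005247	3009269	+		V	V
A	3008654	T	G	X276_13415	S-layer family protein	3005247	3009269	+		T	T
A	5443138	C	T	X276_03000	AAA family ATPase	5441786	5444533	−		E	K
B	863781	T	G	X276_22865	Carbohydrate ABC transporter permease	863698	864525	+		I	M
B	1190011	G	T						Non-coding
B	2052101	G	T	X276_17580	Peptidase S8	2051180	2052916	+		G	C
B	3394324	C	T	X276_11885	16S ribosomal RNA	3393103	3394616	−		T	T
B	4087693	C	A						Non-coding
B	5173544	A	AT	X276_04045	Chemotaxis protein CheC	5173215	5173817	−
B	5443138	C	T	X276_03000	AAA family ATPase	5441786	5444533	−		E	K
C	863781	T	G	X276_22865	Carbohydrate ABC transporter permease	863698	864525	+		I	M
C	968295	C	T	X276_22430	Peptidase S8	967488	969206	+		H	Y
C	2775238	G	T	X276_14460	Cytochrome b5	2775169	2775996	+		E	*
C	2919727	T	A	X276_13825	Hypothetical protein	2919158	2919820	+		S	S
C	3004110	C	T	X276_13420	Collagen-like protein	3003304	3004570	+	Pseudogene	G	G
C	3025567	C	A	X276_13335	Collagen-like protein	3025298	3027013	+		G	G
C	4087693	C	A						Non-coding
C	5443138	C	T	X276_03000	AAA family ATPase	5441786	5444533	−		E	K
C	5649791	C	A						Non-coding
B33	81253	G	A	X276_26470	Prolipoprotein diacylglyceryl transferase	81069	81839	+		G	E
B33	1115679	G	C						Non-coding
B33	1457462	G	A						Non-coding
B33	1913236	G	A	X276_18195	ABC transporter substrate-binding protein	1912234	1913397	+		D	N
B33	3567763	C	T	X276_11100	Methyl-accepting chemotaxis protein	3566625	3568346	−		S	N
B33	4087693	C	A						Non-coding
B33	4257246	C	T	X276_07910	DNA polymerase III subunit epsilon	4256489	4257421	−		S	N
B33	4560040	C	T	X276_06635	Pyruvate, phosphate dikinase	4560023	4562566	−		V	I
B33	5150062	T	A	X276_27350	Hypothetical protein	5146861	5150820	−		T	T
B33	5150524	A	T	X276_27350	Hypothetical protein	5146861	5150820	−		S	S
B33	5150526	A	T	X276_27350	Hypothetical protein	5146861	5150820	−		S	T
B33	5150530	C	T	X276_27350	Hypothetical protein	5146861	5150820	−		V	V
B33	5150532	C	T	X276_27350	Hypothetical protein	5146861	5150820	−		V	M
B33	5150533	A	T	X276_27350	Hypothetical protein	5146861	5150820	−		I	I
B33	5150538	C	T	X276_27350	Hypothetical protein	5146861	5150820	−		V	I
B33	5150545	T	C	X276_27350	Hypothetical protein	5146861	5150820	−		G	G
B33	5150568	T	C	X276_27350	Hypothetical protein	5146861	5150820	−		I	V
B44	3006134	C	A	X276_13415	S-layer family protein	3005247	3009269	+		T	T
B44	3007658	C	A	X276_13415	S-layer family protein	3005247	3009269	+		G	G
B44	4087693	C	A						Non-coding
E15	654069	C	T	X276_23670	Nitrogenase iron protein	653549	654403	+		A	V
E15	685966	C	T	X276_23545	tRNA 2-thiocytidine biosynthesis protein TtcA	685570	686436	+		P	S
E15	724396	GT	G						Non-coding
E15	1809500	CA	C	X276_18715	YggS family pyridoxal phosphate-dependent enzyme	1809001	1809681	+
E15	2376845	G	A	X276_16220	MFS transporter	2376293	2377702	−		Y	Y
E15	2453563	G	A	X276_15915	Sigma-54-dependent Fis family transcriptional regulator	2451932	2453896	+		E	E
E15	2468045	G	A	X276_15855	HlyC/CorC family transporter	2467109	2468398	+		A	T
E15	2482557	C	T	X276_15775	Bifunctional 4-hydroxy-2-oxoglutarate aldolase/2-dehydro-3-deoxy-phosphogluconate aldolase	2482286	2482915	+		A	V
E15	3008051	C	A	X276_13415	S-layer family protein	3005247	3009269	+		T	T
E15	3141441	C	CA	X276_12855	DUF4179 domain-containing protein	3141433	3142683	+
E15	4087693	C	A						Non-coding
E15	4243433	C	CT	X276_07980	MarR family transcriptional regulator	4243239	4243676	−
E28	491837	G	A	X276_24400	MerR family transcriptional regulator	491399	492223	+		E	K
E28	851273	T	G	X276_22910	16S ribosomal RNA	851024	852535	+		*	G
E28	851321	T	G	X276_22910	16S ribosomal RNA	851024	852535	+		*	G
E28	2775807	C	A	X276_14460	Cytochrome b5	2775169	2775996	+		G	G
E28	2775912	T	C	X276_14460	Cytochrome b5	2775169	2775996	+		T	T
E28	3004250	C	A	X276_13420	Collagen-like protein	3003304	3004570	+	Pseudogene	P	Q
E28	3007799	C	A	X276_13415	S-layer family protein	3005247	3009269	+		T	T
E28	3008654	T	G	X276_13415	S-layer family protein	3005247	3009269	+		T	T
E32	2207690	C	CT	X276_16910	IS110 family transposase	2206548	2207848	−	Pseudogene
E32	2775912	T	C	X276_14460	Cytochrome b5	2775169	2775996	+		T	T
E32	3007397	C	A	X276_13415	S-layer family protein	3005247	3009269	+		G	G
E32	3876973	C	A	X276_09805	Glycoside hydrolase	3876787	3877821	−		M	I
E32	4087693	C	A						Non-coding
E32	4243379	C	CAT	X276_07980	MarR family transcriptional regulator	4243239	4243676	−
E32	4960470	G	A	X276_04930	Chemotaxis protein	4958594	4963015	−		T	I
E32	4982628	C	T	X276_04840	Response regulator	4982393	4982745	−	Pseudogene	I	I
E32	5011570	C	T	X276_04700	Non-ribosomal peptide synthase	5010682	5018304	−		W	*
E32	5053669	C	T	X276_04620	Hypothetical protein	5053325	5055736	−		D	N
E32	5083112	C	T	X276_04450	YigZ family protein	5082972	5083619	−		V	I
E32	5084395	C	T	X276_04445	PLP-dependent aminotransferase family protein	5083996	5085438	−		M	I
E32	5275399	G	A	X276_03630	Carboxynorspermidine decarboxylase	5274563	5275702	−		H	Y
E33	2663675	G	A	X276_14895	PFL family protein	2663567	2664922	+		G	R
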
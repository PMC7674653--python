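strain	start	end	size_bp	note
B33	5311613	5311767	155	Intergenic
E15	2982416	2982635	220	Part of the gene X276_13505 encoding DNA mismatch repair protein MutS
E15	5311613	5311767	155	Intergenic
E33	4243635	4244393	759	Part of the gene X276_07980 encoding MarR family transcriptional regulator
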
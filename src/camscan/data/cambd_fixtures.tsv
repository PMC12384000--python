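name	protein	printed_start	printed_end	printed_count	printed_classes	status	notes
Tau-R2	Tau (2N4R)	286	304	1	1-14	clean	source prints start 286 for an 18-mer labelled to 304; canonical 2N4R numbering places the peptide at 287-304, reconciling both the printed end label and the CaMBD serines Ser289/Ser293, so the FASTA record uses start=287
CaMKIIA	CaMKII alpha	296	311	1	1-5-10	clean	reported fingerprint LIL (Leu299/Ile303/Leu308)
GSK3B-CaMBD1	GSK3 beta	81	100	2	1-12;1-5-10	curation-ambiguous	exhaustive curated scan (core anchors) yields five motifs, not the two listed
GSK3B-CaMBD2	GSK3 beta	134	158	4	1-12;1-12;1-14	curation-ambiguous	count given as four but only three classes listed; printed end 158 disagrees with the 24-letter string; the reported Val-Tyr 1-12 fingerprint needs the extended anchor set
GSK3B-CaMBD3	GSK3 beta	193	214	3	1-10;1-10;1-12	curation-ambiguous	curated scan yields four motifs including a 1-8-14 not in the printed list
Cdk5-CaMBD1	Cdk5	17	34	2	1-12;1-12;1-14	label-inconsistent	25 printed letters for an 18-residue span label (17-34), probably a duplication typo; end recomputed as 41; printed count two conflicts with the three classes listed
Cdk5-CaMBD2	Cdk5	133	152	4	1-10;1-10;1-16;1-14	curation-ambiguous	printed 1-16 is not reproducible with the core anchor set; curated scan yields six motifs
ROCK1-CaMBD1	ROCK1	86	105	2	1-12;1-10	clean	printed end 105 disagrees with the 19-letter string; end recomputed as 104
ROCK1-CaMBD2	ROCK1	1133	1151	2	1-12;1-8-13	curation-ambiguous	curated scan additionally finds a 1-8-14 coterminal with the printed 1-8-13 region
CN-CaMBD	calcineurin A	391	414	5	1-16;1-8-14;1-14;1-12;1-10	curation-ambiguous	curated scan also yields five motifs but with two 1-10 and no 1-12; the printed 1-12 requires Met406 as an anchor (extended set)
TGM2-CaMBD1	transglutaminase 2	414	433	3	1-16;1-12;1-5-10	clean	
TGM2-CaMBD2	transglutaminase 2	665	683	5	1-12;1-12;1-8-14;1-10;1-10	curation-ambiguous	printed end 683 disagrees with the 20-letter string (recomputed 684); curated scan yields six motifs with three 1-12 and one 1-10
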
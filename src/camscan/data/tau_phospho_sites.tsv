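position	residue	enzyme	direction	effect_pct	stage	evidence	notes
131	S	CaMKII	phosphorylates			camkii-tau-sites
135	T	CaMKII	phosphorylates			camkii-tau-sites
212	T	CaMKII	phosphorylates			camkii-tau-sites	listed twice in the source survey; stored once with dual citation
214	S	CaMKII	phosphorylates			camkii-tau-sites	listed twice in the source survey; stored once with dual citation
262	S	CaMKII	phosphorylates		pre	camkii-tau-sites;prephos-network	critical for initiation of Tau aggregation
356	S	CaMKII	phosphorylates		pre	camkii-tau-sites;prephos-network	critical for initiation of Tau aggregation
181	T	Cdk5	phosphorylates			cdk5-tau-sites
202	S	Cdk5	phosphorylates			cdk5-tau-sites	hyperphosphorylated in post-mortem AD brain
205	T	Cdk5	phosphorylates			cdk5-tau-sites	hyperphosphorylated in post-mortem AD brain
212	T	Cdk5	phosphorylates			cdk5-tau-sites
217	T	Cdk5	phosphorylates			cdk5-tau-sites
235	S	Cdk5	phosphorylates			cdk5-tau-sites
369	S	Cdk5	phosphorylates			cdk5-tau-sites	possible typo for Ser396 in the source; transcribed as printed
404	S	Cdk5	phosphorylates			cdk5-tau-sites
262	S	Cdk5	phosphorylates		pre	prephos-network	prephosphorylation opening further sites
356	S	Cdk5	phosphorylates		pre	prephos-network	prephosphorylation opening further sites
231	T	GSK3B	phosphorylates		hyper	hyperphos-network
235	S	GSK3B	phosphorylates		hyper	hyperphos-network
396	S	GSK3B	phosphorylates		hyper	hyperphos-network
404	S	GSK3B	phosphorylates		hyper	hyperphos-network
289	S	GSK3B	phosphorylates			tau-cambd-serines	inside the Tau R2 CaMBD; phosphorylated in AD
293	S	GSK3B	phosphorylates			tau-cambd-serines	inside the Tau R2 CaMBD; phosphorylated in AD
289	S	MAPK	phosphorylates			tau-cambd-serines	p38 MAPK; inside the Tau R2 CaMBD
293	S	MAPK	phosphorylates			tau-cambd-serines	p38 MAPK; inside the Tau R2 CaMBD
262	S	MARK4	phosphorylates		hyper	mark4-tau-sites	hyperphosphorylated by MARK4 in AD brain
262	S	CN	dephosphorylates	63	dephos	cn-dephos-rates	R1 domain; percent decrease in phosphorylation
396	S	CN	dephosphorylates	78	dephos	cn-dephos-rates	R4 domain; percent decrease in phosphorylation
199	S	CN	dephosphorylates	38		cn-dephos-rates
217	T	CN	dephosphorylates	32		cn-dephos-rates
422	S	CN	dephosphorylates	32		cn-dephos-rates
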
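sample_id	gene	contig	position	ref	alt	consequence_class	aa_change	af_global	af_ancestry	clinvar_class	acmg_class	mcap_score	zygosity
1010	QARS	3	49137655	G	A	nonsynonymous	p.Arg367Cys	3.19e-05		absent	LP		het
1172	CLN8	8	1719428	C	T	nonsynonymous	p.Arg70Cys	0.0		absent	LP		het
1193	PPT1	1	40558081	T	G	nonsynonymous	p.Thr25Pro	0.0		absent	P		het
1193	CSTB	21	45194641	C	G	nonsynonymous	n.104G>C	0.0003		P	P	0.31	het
1001	FKRP	19	47259533	C	A	nonsynonymous	p.Leu276Ile	0.0014		P	P	0.12	het
1012	TTR	18	29178618	G	A	nonsynonymous	p.Val142Ile	0.0048		P	P	0.05	het
1028	TTR	18	29178618	G	A	nonsynonymous	p.Val142Ile	0.0048		P	P	0.05	het
1058	CALM3	19	47112212	A	G	nonsynonymous	p.Asp96Gly	0.0		absent	LP	0.62	het
1117	TTR	18	29178618	G	A	nonsynonymous	p.Val142Ile	0.0048		P	P	0.05	het
1127	TTR	18	29178618	G	A	nonsynonymous	p.Val142Ile	0.0048		P	P	0.05	het
1132	DSP	6	7571745	C	T	nonsynonymous	p.Gln611X	0.0		absent	P		het
1214	KCNH2	7	150654393	C	CAG	nonsynonymous	p.Thr371_Glu372fs	0.0		absent	P		het
1042	SCN1A	2	166848000	G	A	nonsynonymous	p.Ala100Thr	0.0002		VUS	VUS	0.04	het
1077	MYH7	14	23890000	C	T	nonsynonymous	p.Arg500Cys	0.0005		VUS	VUS	0.01	het
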
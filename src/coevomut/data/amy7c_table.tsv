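site	wt_codon	amino_acid	codon	count
89	GGC	A	GCG	2
89	GGC	C	TTT	2
89	GGC	D	CTG	1
89	GGC	E	GAG	1
89	GGC	F	TTT	1
89	GGC	G	GGG	5
89	GGC	G	GGT	3
89	GGC	L	CTG	1
89	GGC	N	AAT	1
89	GGC	Q	CAG	1
89	GGC	R	CGT	3
89	GGC	R	CGC	3
89	GGC	T	ACA	1
95	GAT	H	CAT	1
95	GAT	R	CGG	1
100	CAT	I	ATT	2
100	CAT	M	ATG	4
100	CAT	N	AAT	2
100	CAT	Q	CAG	1
100	CAT	R	CGG	1
100	CAT	R	CGT	3
100	CAT	S	AGT	1
144	GAT	E	GAG	3
144	GAT	G	GGG	4
144	GAT	G	GGT	4
144	GAT	R	CGG	1
144	GAT	V	GTT	3
144	GAT	W	TGG	1
147	ACT	C	TGT	3
147	ACT	N	AAT	3
147	ACT	P	CCT	3
147	ACT	R	CGT	4
147	ACT	R	CGC	3
147	ACT	S	TCT	1
147	ACT	V	GTG	3
197	AAT	A	CGC	1
197	AAT	C	TGT	7
197	AAT	D	GAT	1
197	AAT	G	GGG	3
197	AAT	K	AAG	1
197	AAT	M	ATG	2
197	AAT	Q	CAG	1
197	AAT	R	AGG	1
197	AAT	S	TCG	5
197	AAT	S	AGT	1
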
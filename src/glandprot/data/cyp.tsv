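beebase_id	gene_name	accession	extra_accessions	nPcG	fPcG	nTG	fTG	nMG	fMG	mg_selective	abundance
GB19967	CYP9Q3	gi|328781973	gi|328781975;gi|328781977;gi|48098075	0	0	0	0	0	2	S	-
GB19820	CYP9Q1	gi|48098085		0	0	0	0	0	8	S	-
GB13748	CYP9S1	gi|48098081		4	0	20	19	4	20	-	-
GB11943	CYP305D1	gi|66512130		0	0	0	0	117	40	S	A
GB11754	CYP6AS8	gi|328785290	gi|66523006	0	0	0	0	245	249	S	A
GB19797	CYP336A1	gi|328789667		0	0	8	4	0	1	-	-
GB19306	CYP6BD1	gi|328784477		51	61	0	0	0	17	-	-
GB16447	CYP315A1	gi|328784025	gi|328784023	0	0	0	0	0	2	S	-
GB15793	CYP6AS4	gi|328785304		22	28	0	0	0	1	-	-
GB11027	CYP6AS11	gi|110762372		0	0	0	0	100	43	S	A
GB15681	CYP6AS3	gi|110765954	gi|66565910	14	13	0	0	0	0	-	-
GB17434	CYP6AS5	gi|94158657		0	0	0	0	0	7	S	-
GB18052	CYP6AS7	gi|66522973		8	1	12	4	1	8	-	-
GB17793	CYP9Q2	gi|48098073		0	0	0	0	0	3	S	-
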
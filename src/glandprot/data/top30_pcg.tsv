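accession	description	nPcG	fPcG	merged_printed	prev_rank
gi|328789361	p. transketolase isoform 1	2207	2084	4291	3
gi|66503776	p. transketolase isoform 2	2208	2082	4290	6
gi|328787941	p. fatty acid synthase-like	1016	2821	3837	1
gi|66530142	p. ATP-citrate synthase isoform 1	583	1387	1970	2
gi|48142692	p. glyceraldehyde-3-phosphate dehydrogenase 2 isoform 1	491	785	1276	16
gi|110748949	p. fructose-bisphosphate aldolase-like	368	887	1255	10
gi|66547450	p. 60 kDa heat shock protein, mitochondrial-like	662	499	1161	9
gi|328785411	p. acetyl-CoA carboxylase-like	370	645	1015	5
gi|48097100	p. 3-ketoacyl-CoA thiolase, mitochondrial-like	461	488	949	15
gi|328785025	p. ATP synthase subunit beta, mitochondrial	367	511	878	8
gi|328788708	p. pyruvate carboxylase, mitochondrial-like	217	451	668	4
gi|297591985	actin related protein 1	359	267	626	31
gi|297591987	actin related protein 1	359	267	626	31
gi|300807169	fatty acyl-CoA reductase 1	151	380	531	14
gi|328778238	p. NADP-dependent malic enzyme isoform 1	153	351	504	7
gi|336391183	ATP synthase lipid-binding protein, mitochondrial	291	210	501	-
gi|336391185	ATP synthase lipid-binding protein, mitochondrial	291	210	501	-
gi|328777397	p. alkyldihydroxyacetonephosphate synthase-like	239	231	470	34
gi|328786450	p. ATP synthase subunit delta, mitochondrial isoform 1	185	242	427	143
gi|328786452	p. ATP synthase subunit delta, mitochondrial isoform 2	185	242	427	143
gi|66517317	p. ATP synthase subunit delta, mitochondrial isoform 3	185	242	427	143
gi|48100966	p. ATP synthase subunit alpha, mitochondrial isoform 1	165	255	420	11
gi|66531797	p. ubiquitin-40S ribosomal protein S27a	150	266	416	307
gi|328783160	p. transaldolase	141	261	402	23
gi|110756311	p. ubiquitin-60S ribosomal protein L40 isoform 1	141	259	400	182
gi|328780726	p. polyubiquitin-A-like	141	259	400	182
gi|328780728	p. polyubiquitin-A-like	141	259	400	182
gi|328786389	p. pyruvate kinase-like	183	217	400	12
gi|328790046	p. ubiquitin-60S ribosomal protein L40 isoform 2	141	259	400	182
gi|328790050	p. ubiquitin-60S ribosomal protein L40 isoform 4	141	259	400	182
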
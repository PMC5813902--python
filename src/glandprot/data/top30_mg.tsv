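accession	description	nMG	fMG	merged_printed
gi|328787941	p. fatty acid synthase-like	2118	4263	6381
gi|48097100	p. 3-ketoacyl-CoA thiolase, mitochondrial-like	2682	1140	3822
gi|201023353	esterase A2	881	1128	2009
gi|328789361	p. transketolase isoform 1	748	644	1392
gi|66503776	p. transketolase isoform 2	745	640	1385
gi|297591985	actin related protein 1	374	705	1079
gi|297591987	actin related protein 1	374	705	1079
gi|332801003	acyl-CoA synthetase family member 2, mitochondrial precursor	682	121	803
gi|328785025	p. ATP synthase subunit beta, mitochondrial	348	373	721
gi|66547450	p. 60 kDa heat shock protein, mitochondrial-like	399	208	607
gi|295849268	superoxide dismutase 1	411	194	605
gi|66548355	p. acyl-CoA synthetase family member 2, mitochondrial-like, partial	535	0	535
gi|328786450	p. ATP synthase subunit delta, mitochondrial isoform 1	248	253	501
gi|328786452	p. ATP synthase subunit delta, mitochondrial isoform 2	248	253	501
gi|66517317	p. ATP synthase subunit delta, mitochondrial isoform 3	248	253	501
gi|66523006	p. probable cytochrome P450 6a14 isoform 1	239	245	484
gi|66511554	p. glucosylceramidase-like isoform 1	111	369	480
gi|328785411	p. acetyl-CoA carboxylase-like	229	225	454
gi|328785413	p. acetyl-CoA carboxylase-like isoform 2	229	225	454
gi|110760701	p. 3-hydroxyacyl-CoA dehydrogenase type-2-like	315	131	446
gi|336391183	ATP synthase lipid-binding protein, mitochondrial	269	176	445
gi|336391185	ATP synthase lipid-binding protein, mitochondrial	269	176	445
gi|66530142	p. ATP-citrate synthase isoform 1	259	160	419
gi|328783869	p. basement membrane-specific heparan sulfate proteoglycan core protein-like	120	296	416
gi|48100966	p. ATP synthase subunit alpha, mitochondrial isoform 1	194	218	412
gi|328783535	p. transitional endoplasmic reticulum ATPase TER94 isoform 1	171	235	406
gi|399220320	cuticular protein 28 precursor	66	329	395
gi|328785290	p. probable cytochrome P450 6a14	208	186	394
gi|110757387	p. ecdysteroid UDP-glucosyltransferase-like	133	258	391
gi|110756311	p. ubiquitin-60S ribosomal protein L40 isoform 1	176	208	384
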
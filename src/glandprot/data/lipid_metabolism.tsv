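pathway_id	pathway_name	accession	description	(n+f)PcG	(n+f)TG	(n+f)MG
ame00061	Fatty acid biosynthesis	gi|328787941	p. fatty acid synthase-like	3837	51	6381
ame00061	Fatty acid biosynthesis	gi|328785411	p. acetyl-CoA carboxylase-like	1015	45	454
ame00062	Fatty acid elongation	gi|48097100	p. 3-ketoacyl-CoA thiolase, mitochondrial-like	949	70	3822
ame00062	Fatty acid elongation	gi|66507594	p. trifunctional enzyme subunit beta, mitochondrial-like	114	82	113
ame00062	Fatty acid elongation	gi|328778689	p. probable enoyl-CoA hydratase, mitochondrial	77	39	107
ame00062	Fatty acid elongation	gi|66519936	p. trifunctional enzyme subunit alpha, mitochondrial-like	173	131	168
ame00071	Fatty acid degradation	gi|66499429	p. probable medium-chain specific acyl-CoA dehydrogenase, mitochondrial-like	141	64	380
ame00071	Fatty acid degradation	gi|328778689	p. probable enoyl-CoA hydratase, mitochondrial	77	39	107
ame00071	Fatty acid degradation	gi|66519936	p. trifunctional enzyme subunit alpha, mitochondrial-like	173	131	168
ame00071	Fatty acid degradation	gi|66530423	p. aldehyde dehydrogenase, mitochondrial isoform 1	84	75	349
ame00071	Fatty acid degradation	gi|66507594	p. trifunctional enzyme subunit beta, mitochondrial-like	114	82	113
ame00072	Synthesis and degradation of ketone bodies	gi|66535270	p. succinyl-CoA:3-ketoacid-coenzyme A transferase 1, mitochondrial-like	97	72	109
ame00072	Synthesis and degradation of ketone bodies	gi|48141273	p. hydroxymethylglutaryl-CoA synthase 1	132	57	34
ame00561	Glycerolipid metabolism	gi|66530423	p. aldehyde dehydrogenase, mitochondrial isoform 1	84	75	349
ame00564	Glycerophospholipid metabolism	gi|62526114	glycerol-3-phosphate dehydrogenase	88	101	92
ame00564	Glycerophospholipid metabolism	gi|328784660	p. glycerol-3-phosphate dehydrogenase, mitochondrial-like	79	104	111
ame00565	Ether lipid metabolism	gi|328777397	p. alkyldihydroxyacetonephosphate synthase-like	470	0	0
ame00600	Sphingolipid metabolism	gi|66511554	p. glucosylceramidase-like isoform 1	4	0	480
ame01040	Biosynthesis of unsaturated fatty acids	gi|66519936	p. trifunctional enzyme subunit alpha, mitochondrial-like	173	131	168
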
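accession	description	nTG	fTG	merged_printed	prev_rank
gi|66531434	p. v-type proton ATPase subunit B-like	1329	1517	2846	4
gi|66515272	p. v-type proton ATPase catalytic subunit A-like isoform 1	1267	1132	2399	3
gi|58531215	ADP/ATP translocase	732	845	1577	6
gi|48094573	p. hypothetical protein LOC408608	803	719	1522	9
gi|328785025	p. ATP synthase subunit beta, mitochondrial	636	631	1267	7
gi|66556287	p. v-type proton ATPase subunit E isoform 3	441	442	883	33
gi|297591985	actin related protein 1	394	400	794	20
gi|297591987	actin related protein 1	394	400	794	20
gi|66553147	p. v-type proton ATPase subunit G	401	286	687	100
gi|328777212	p. spectrin alpha chain-like	360	323	683	1
gi|62526112	elongation factor 1-alpha	339	268	607	20
gi|328787929	p. spectrin beta chain	302	274	576	5
gi|48100966	p. ATP synthase subunit alpha, mitochondrial isoform 1	287	267	554	10
gi|328792073	p. v-type proton ATPase subunit H isoform 2	296	248	544	13
gi|328783869	p. basement membrane-specific heparan sulfate proteoglycan core protein-like	363	175	538	2
gi|328787562	p. tubulin alpha-1 chain-like	260	251	511	14
gi|66535209	p. tubulin alpha-1 chain-like	261	243	504	78
gi|328786450	p. ATP synthase subunit delta, mitochondrial isoform 1	257	241	498	107
gi|328786452	p. ATP synthase subunit delta, mitochondrial isoform 2	257	241	498	107
gi|66517317	p. ATP synthase subunit delta, mitochondrial isoform 3	257	241	498	107
gi|66515294	p. v-type proton ATPase subunit D 1-like isoform 1	269	210	479	148
gi|66547450	p. 60 kDa heat shock protein, mitochondrial-like	252	222	474	11
gi|336391183	ATP synthase lipid-binding protein, mitochondrial	213	230	443	589
gi|336391185	ATP synthase lipid-binding protein, mitochondrial	213	230	443	589
gi|48142692	p. glyceraldehyde-3-phosphate dehydrogenase 2 isoform 1	215	211	426	29
gi|66531797	p. ubiquitin-40S ribosomal protein S27a	193	188	381	240
gi|110756311	p. ubiquitin-60S ribosomal protein L40 isoform 1	182	184	366	240
gi|328780726	p. polyubiquitin-A-like	182	184	366	240
gi|328780728	p. polyubiquitin-A-like	182	184	366	240
gi|328790046	p. ubiquitin-60S ribosomal protein L40 isoform 2	182	184	366	240
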
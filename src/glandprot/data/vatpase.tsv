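accession	description	domain	nPcG	fPcG	nTG	fTG	nMG	fMG
gi|66515272	p. v-type proton ATPase catalytic subunit A-like isoform 1	V1	52	68	1267	1132	77	139
gi|66531434	p. v-type proton ATPase subunit B-like	V1	61	67	1329	1517	74	120
gi|328781744	p. v-type proton ATPase subunit C	V1	7	6	116	113	12	6
gi|328781786	p. v-type proton ATPase subunit C-like	V1	6	6	28	21	4	10
gi|66515294	p. v-type proton ATPase subunit D 1-like isoform 1	V1	4	6	269	210	16	22
gi|66556287	p. v-type proton ATPase subunit E isoform 3	V1	32	32	441	442	32	34
gi|66529931	p. v-type proton ATPase subunit F 1-like	V1	0	6	210	117	2	4
gi|66553147	p. v-type proton ATPase subunit G	V1	16	12	401	286	33	34
gi|328792071	p. v-type proton ATPase subunit H isoform 1	V1	0	0	284	0	41	0
gi|328792073	p. v-type proton ATPase subunit H isoform 2	V1	26	31	296	248	41	51
gi|328777195	p. v-type proton ATPase 116 kDa subunit a isoform 1-like	V0	12	4	117	105	8	16
gi|328785772	p. v-type proton ATPase 116 kDa subunit a isoform 1-like isoform 1	V0	0	0	16	18	0	4
gi|328776893	p. probable V-type proton ATPase 116 kDa subunit a-like	V0	6	8	42	27	5	4
gi|66548758	p. v-type proton ATPase subunit d	V0	14	15	101	124	4	16
gi|66524947	p. v-type proton ATPase subunit e 2-like	V0	0	2	13	9	0	0
gi|58585082	vacuolar H+ ATP synthase 16 kDa proteolipid subunit	V0	1	4	27	36	1	4
gi|48099854	p. v-type proton ATPase 21 kDa proteolipid subunit-like	V0	1	0	11	16	0	0
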
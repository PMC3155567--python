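gene_symbol	accession	fold_change	sex_specificity	is_znf
ZNF382	NM_032825	1.35	M	1
LOC100128439	BC032415	1.34	M	0
ZNF682	NM_033196	1.31	M	1
ZNF544	NM_014480	1.27	M	1
ZNF563	NM_145276	1.26	M	1
RTN2	NM_206901	1.25	M	0
MAST1	NM_014975	1.25	M	0
ACER1	NM_133492	1.22	M	0
ZNF28	NM_006969	1.21	M	1
ANGPTL4	NM_139314	1.21	M	0
ZNF566	NM_032838	1.21	M	1
ZNF542	NR_033418	1.20	M	1
TLE2	NM_003260	1.20	M	0
ZNF829	NM_001171979	1.20	M	1
DOT1L	NM_032482	1.19	M	0
ZNF549	NM_153263	1.17	M	1
ZNF329	NM_024620	1.17	M	1
ZNF8	NM_021089	1.17	M	1
DPY19L3	NM_207325	1.15	M	0
REEP6	NM_138393	-1.15	F	0
APOC4	NM_001646	-1.18	F	0
NFIX	NM_002501	-1.19	F	0
SLC35E1	NM_024881	-1.20	F	0
CCDC123	NM_032816	-1.20	F	0
ZNF766	NM_001010851	-1.24	F	1
KANK2	NM_015493	-1.25	F	0
GRLF1	NM_004491	-1.25	F	0
SIGLEC11	NM_052884	-1.27	F	0
RAD23A	NM_005053	-1.31	F	0
CYP2B7P1	AK307933	-1.36	F	0
RAB3A	NM_002866	-1.37	F	0
LDLR	NM_000527	-1.42	F	0
PEG3	NM_006210	-1.50	F	1
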
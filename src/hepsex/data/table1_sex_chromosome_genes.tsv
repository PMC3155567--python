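gene_symbol	accession	fold_change	chrom
XIST	NR_001564	-24.12	chrX
FRMD7	NM_194277	-2.53	chrX
ZFX	NM_003410	-1.89	chrX
IL1RAPL1	AJ243874	-1.86	chrX
PNPLA4	NM_004650	-1.71	chrX
KDM6A	NM_021140	-1.66	chrX
HDHD1A	NM_012080	-1.62	chrX
GYG2	NM_003918	-1.57	chrX
STS	NM_000351	-1.53	chrX
ENOX2	NM_182314	-1.48	chrX
EIF1AX	NM_001412	-1.46	chrX
CHM	NM_000390	-1.43	chrX
EDA	NM_001399	-1.42	chrX
KDM5C	NM_004187	-1.41	chrX
MUM1L1	NM_152423	-1.38	chrX
-	AK022479	-1.37	chrX
CXorf38	NM_144970	-1.35	chrX
MAP7D3	NM_024597	-1.34	chrX
VCX2	NM_016378	-1.33	chrX
PHF6	NM_032458	-1.32	chrX
NCRNA00183	NR_024582	-1.31	chrX
MBNL3	NM_133486	-1.29	chrX
GPR82	NM_080817	-1.25	chrX
SMC1A	NM_006306	-1.25	chrX
RIBC1	NM_001031745	-1.24	chrX
-	ENST_00000436419	-1.22	chrX
TTC3L	NR_030737	-1.21	chrX
CXorf15	NM_018360	-1.21	chrX
LOC644538	NM_001163438	-1.20	chrX
FMR1	NM_002024	-1.19	chrX
ZMAT1	NM_032441	-1.19	chrX
OPHN1	NM_002547	-1.18	chrX
PGRMC1	NM_006667	-1.17	chrX
DDX3X	NM_001356	-1.16	chrX
GJB1	NM_001097642	-1.16	chrX
STAG2	NM_006603	-1.15	chrX
NXF3	NM_022052	1.19	chrX
-	AK124653	1.29	chrX
-	AK123627	1.30	chrX
TAF7L	NM_024885	1.42	chrX
COL4A5	NM_033381	1.52	chrX
USP9Y	NM_004654	105.11	chrY
ZFY	NM_003411	58.63	chrY
TTTY15	NR_001545	35.53	chrY
EIF1AY	NM_004681	35.11	chrY
CYorf15A	NM_001005852	32.75	chrY
CYorf15B	BC035312	29.10	chrY
UTY	NM_182660	23.68	chrY
NLGN4Y	NR_028319	19.66	chrY
NCRNA00185	NR_001544	19.01	chrY
KDM5D	NM_004653	14.19	chrY
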
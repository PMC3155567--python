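gene_symbol	alternate_name	fold_change	p_value	composite_score	agreement_4_populations	agreement_9_hybrids
ZFX	-	-1.89	0.0	16	4	9/9
PNPLA4	-	-1.71	0.0	16	4	9/9
KDM6A	UTX	-1.66	0.0	16	4	9/9
HDHD1A	-	-1.62	0.0	16	4	8/9
RPS4X	-	-1.48	0.0	16	4	9/9
EIF1AX	-	-1.46	0.0	16	4	9/9
KDM5C	JARID1C	-1.41	0.0	16	4	9/9
ZRSR2	-	-1.18	1.52e-21	16	4	NA
FUNDC1	-	-1.11	7.28e-17	16	4	8/9
DDX3X	-	-1.16	1.18e-14	16	4	9/9
UBA1	UBE1	-1.12	1.11e-10	14	4	9/9
EIF2S3	-	-1.17	1.28e-07	13	4	9/9
USP9X	-	-1.12	7.20e-05	12	4	9/9
PRKX	-	-1.07	NA	13	4	7/9
CDK16	PCTK1	1.01	NA	9	4	7/7
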
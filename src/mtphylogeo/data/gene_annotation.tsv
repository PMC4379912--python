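# Standard human mitochondrial gene map, 1-based inclusive coordinates on the
# 16,569-bp reference frame.  kind: protein | tRNA | rRNA.  strand: H | L.
# Everything in 577-16023 not covered below is intergenic noncoding; the
# control region is the circular span 16024-576.
Name	Start	End	Kind	Strand
TF	577	647	tRNA	H
RNR1	648	1601	rRNA	H
TV	1602	1670	tRNA	H
RNR2	1671	3229	rRNA	H
TL1	3230	3304	tRNA	H
ND1	3307	4262	protein	H
TI	4263	4331	tRNA	H
TQ	4329	4400	tRNA	L
TM	4402	4469	tRNA	H
ND2	4470	5511	protein	H
TW	5512	5579	tRNA	H
TA	5587	5655	tRNA	L
TN	5657	5729	tRNA	L
TC	5761	5826	tRNA	L
TY	5826	5891	tRNA	L
CO1	5904	7445	protein	H
TS1	7446	7514	tRNA	L
TD	7518	7585	tRNA	H
CO2	7586	8269	protein	H
TK	8295	8364	tRNA	H
ATP8	8366	8572	protein	H
ATP6	8527	9207	protein	H
CO3	9207	9990	protein	H
TG	9991	10058	tRNA	H
ND3	10059	10404	protein	H
TR	10405	10469	tRNA	H
ND4L	10470	10766	protein	H
ND4	10760	12137	protein	H
TH	12138	12206	tRNA	H
TS2	12207	12265	tRNA	H
TL2	12266	12336	tRNA	H
ND5	12337	14148	protein	H
ND6	14149	14673	protein	L
TE	14674	14742	tRNA	L
CYB	14747	15887	protein	H
TT	15888	15953	tRNA	H
TP	15956	16023	tRNA	L
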
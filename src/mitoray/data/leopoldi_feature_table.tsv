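Name	Type	Strand	Start	Stop	Intergenic	Length	Codons
tRNA-Phe	tRNA	+	1	69	0	69	-
12S rRNA	rRNA	+	70	1030	0	961	-
tRNA-Val	tRNA	+	1031	1102	19	72	-
16S rRNA	rRNA	+	1122	2788	3	1667	-
tRNA-Leu	tRNA	+	2792	2866	0	75	-
ND1	PCG	+	2867	3841	1	975	ATG/TAA
tRNA-Ile	tRNA	+	3843	3910	4	68	-
tRNA-Gln	tRNA	-	3915	3986	0	72	-
tRNA-Met	tRNA	+	3987	4056	0	70	-
ND2	PCG	+	4057	5103	-1	1047	ATG/TAA
tRNA-Trp	tRNA	+	5103	5172	1	70	-
tRNA-Ala	tRNA	-	5174	5243	1	70	-
tRNA-Asn	tRNA	-	5245	5317	4	73	-
tRNA-Cys	tRNA	-	5351	5419	5	69	-
tRNA-Tyr	tRNA	-	5425	5493	1	69	-
COX1	PCG	+	5495	7048	6	1554	GTG/TAG
tRNA-Ser 2	tRNA	-	7055	7125	0	71	-
tRNA-Asp	tRNA	+	7126	7196	3	71	-
COX2	PCG	+	7200	7890	0	691	ATG/T(AA)
tRNA-Lys	tRNA	+	7891	7964	1	74	-
ATP8	PCG	+	7966	8133	-10	168	ATG/TAA
ATP6	PCG	+	8124	8807	-1	683	ATG/TAA
COX3	PCG	+	8807	9592	5	786	ATG/TAA
tRNA-Gly	tRNA	+	9598	9668	0	71	-
ND3	PCG	+	9669	10,019	-1	351	ATG/TAA
tRNA-Arg	tRNA	+	10,019	10,089	0	71	-
ND4L	PCG	+	10,090	10,386	-7	297	ATG/TAA
ND4	PCG	+	10,380	11,760	3	1381	ATG/T(AA)
tRNA-His	tRNA	+	11,764	11,832	1	69	-
tRNA-Ser	tRNA	+	11,834	11,900	0	72	-
tRNA-Leu	tRNA	+	11,903	11,974	0	72	-
ND5	PCG	+	11,975	13,810	-4	1836	ATG/TAA
ND6	PCG	-	13,807	14,328	0	522	ATG/TAG
tRNA-Glu	tRNA	-	14,319	14,397	1	69	-
CYTB	PCG	+	14,399	15,541	4	1143	ATG/TAA
tRNA-Thr	tRNA	+	15,546	15,616	8	71	-
tRNA-Pro	tRNA	-	15,652	15,694	0	70	-
D-loop	CR		15,694	17,504		1810	-
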
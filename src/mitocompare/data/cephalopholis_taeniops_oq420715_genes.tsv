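Genes	Start	Stop	Strand	Size (bp)	Intergenic Nucleotide	Anticodon	Start Codon	Stop Codon
tRNA-Phe (F)	1	70	H	70	0	TTC	.	.
12S rRNA	71	1023	H	953	0	.	.	.
tRNA-Val (V)	1024	1095	H	72	0	GTA	.	.
16S rRNA	1096	2807	H	1712	0	.	.	.
tRNA-Leu (L2)	2808	2882	H	75	0	TTA	.	.
ND1	2883	3857	H	975	5	.	ATG	TAA
tRNA-Ile (I)	3863	3932	H	70	-1	ATC	.	.
tRNA-Gln (Q)	3932	4002	L	71	0	CAA	.	.
tRNA-Met (M)	4003	4072	H	70	0	ATG	.	.
ND2	4073	5118	H	1046	0	.	ATG	TA-
tRNA-Trp (W)	5119	5189	H	71	1	TGA	.	.
tRNA-Ala (A)	5191	5259	L	69	0	GCA	.	.
tRNA-Asn (N)	5260	5332	L	73	37	AAC	.	.
tRNA-Cys (C)	5370	5437	L	68	0	TGC	.	.
tRNA-Tyr (Y)	5438	5508	L	71	1	TAC	.	.
COI	5510	7060	H	1551	0	.	GTG	TAA
tRNA-Ser (S2)	7061	7131	L	71	1	TCA	.	.
tRNA-Asp (D)	7133	7205	H	73	8	GAC	.	.
COII	7214	7904	H	691	0	.	ATG	T--
tRNA-Lys (K)	7905	7977	H	73	1	AAA	.	.
ATP8	7979	8146	H	168	-10	.	ATG	TAA
ATP6	8137	8819	H	683	0	.	TTG	TA-
COIII	8820	9604	H	785	0	.	ATG	TA-
tRNA-Gly (G)	9605	9676	H	72	0	GGA	.	.
ND3	9677	10,025	H	349	0	.	ATG	T--
tRNA-Arg (R)	10,026	10,094	H	69	0	CGA	.	.
ND4L	10,095	10,391	H	297	-7	.	ATG	TAA
ND4	10,385	11,765	H	1381	0	.	ATG	T--
tRNA-His (H)	11,766	11,835	H	70	0	CAC	.	.
tRNA-Ser (S1)	11,836	11,907	H	72	6	AGC	.	.
tRNA-Leu (L1)	11,914	11,986	H	73	0	CTA	.	.
ND5	11,987	13,825	H	1839	-4	.	ATG	TAA
ND6	13,822	14,343	L	522	0	.	ATG	TAA
tRNA-Glu (E)	14,344	14,412	L	69	4	GAA	.	.
Cyt b	14,417	15,557	H	1141	0	.	ATG	T--
tRNA-Thr (T)	15,558	15,630	H	73	-1	ACA	.	.
tRNA-Pro (P)	15,630	15,699	L	70	0	CCA	.	.
Control region (CR)	15,700	16,572	H	873	.	.	.	.
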
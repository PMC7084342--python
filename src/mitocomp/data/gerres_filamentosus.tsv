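#label=Gerres_filamentosus length=16673 circular=1
name	category	strand	start	end	anticodon	start_codon	stop_codon
tRNA-Phe	tRNA	H	1	71	GAA
12S-rRNA	rRNA	H	72	1053
tRNA-Val	tRNA	H	1054	1122	TAC
16S-rRNA	rRNA	H	1124	2813
tRNA-Leu	tRNA	H	2814	2887	TAA
ND1	PCG	H	2888	3862		ATG	TAA
tRNA-Ile	tRNA	H	3870	3940	GAT
tRNA-Gln	tRNA	L	3952	4026	TTG
tRNA-Met	tRNA	H	4036	4104	CAT
ND2	PCG	H	4105	5151		ATG	TAG
tRNA-Trp	tRNA	H	5152	5222	TCA
tRNA-Ala	tRNA	L	5224	5292	TGC
tRNA-Asn	tRNA	L	5294	5366	GTT
tRNA-Cys	tRNA	L	5402	5468	GCA
tRNA-Tyr	tRNA	L	5469	5539	GTA
COXI	PCG	H	5541	7091		GTG	TAA
tRNA-Ser	tRNA	L	7092	7162	TGA
tRNA-Asp	tRNA	H	7166	7237	GTC
COXII	PCG	H	7247	7937		ATG	T
tRNA-Lys	tRNA	H	7938	8011	TTT
ATP8	PCG	H	8013	8180		ATG	TAA
ATP6	PCG	H	8171	8854		ATG	TAA
COXIII	PCG	H	8854	9638		ATG	TA
tRNA-Gly	tRNA	H	9639	9708	TCC
ND3	PCG	H	9709	10057		ATG	T
tRNA-Arg	tRNA	H	10058	10126	TCG
ND4L	PCG	H	10127	10423		ATG	TAA
ND4	PCG	H	10417	11797		ATG	T
tRNA-His	tRNA	H	11798	11866	GTG
tRNA-Ser	tRNA	H	11867	11934	GCT
tRNA-Leu	tRNA	H	11939	12011	TAG
ND5	PCG	H	12012	13850		ATG	TAA
ND6	PCG	L	13847	14368		ATG	TAG
tRNA-Glu	tRNA	L	14369	14437	TTC
CYTB	PCG	H	14442	15582		ATG	T
tRNA-Thr	tRNA	H	15583	15655	TGT
tRNA-Pro	tRNA	L	15655	15726	TGG
D-loop	control	H	15727	16673
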
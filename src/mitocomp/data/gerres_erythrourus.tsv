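#label=Gerres_erythrourus length=16728 circular=1
name	category	strand	start	end	anticodon	start_codon	stop_codon
tRNA-Phe	tRNA	H	1	70	GAA
12S-rRNA	rRNA	H	71	1022
tRNA-Val	tRNA	H	1023	1093	TAC
16S-rRNA	rRNA	H	1094	2825
tRNA-Leu	tRNA	H	2826	2899	TAA
ND1	PCG	H	2900	3874		ATG	TAA
tRNA-Ile	tRNA	H	3880	3951	GAT
tRNA-Gln	tRNA	L	3957	4027	TTG
tRNA-Met	tRNA	H	4065	4133	CAT
ND2	PCG	H	4134	5179		ATG	TA
tRNA-Trp	tRNA	H	5180	5251	TCA
tRNA-Ala	tRNA	L	5253	5321	TGC
tRNA-Asn	tRNA	L	5324	5396	GTT
tRNA-Cys	tRNA	L	5434	5501	GCA
tRNA-Tyr	tRNA	L	5502	5572	GTA
COXI	PCG	H	5574	7124		GTG	TAA
tRNA-Ser	tRNA	L	7125	7195	TGA
tRNA-Asp	tRNA	H	7199	7270	GTC
COXII	PCG	H	7281	7971		ATG	T
tRNA-Lys	tRNA	H	7972	8046	TTT
ATP8	PCG	H	8055	8222		ATG	TAA
ATP6	PCG	H	8216	8895		ATA	TA
COXIII	PCG	H	8896	9680		ATG	TA
tRNA-Gly	tRNA	H	9682	9751	TCC
ND3	PCG	H	9752	10100		ATG	T
tRNA-Arg	tRNA	H	10101	10169	TCG
ND4L	PCG	H	10170	10466		ATG	TAA
ND4	PCG	H	10460	11840		GTG	T
tRNA-His	tRNA	H	11841	11909	GTG
tRNA-Ser	tRNA	H	11910	11977	GCT
tRNA-Leu	tRNA	H	11983	12056	TAG
ND5	PCG	H	12058	13898		ATG	TA
ND6	PCG	L	13909	14430		ATG	TAA
tRNA-Glu	tRNA	L	14431	14500	TTC
CYTB	PCG	H	14531	15671		ATG	T
tRNA-Thr	tRNA	H	15672	15744	TGT
tRNA-Pro	tRNA	L	15746	15817	TGG
D-loop	control	H	15818	16728
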
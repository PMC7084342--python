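#label=Gerres_decacanthus length=16871 circular=1
name	category	strand	start	end	anticodon	start_codon	stop_codon
tRNA-Phe	tRNA	H	1	71	GAA
12S-rRNA	rRNA	H	72	1053
tRNA-Val	tRNA	H	1054	1124	TAC
16S-rRNA	rRNA	H	1125	2867
tRNA-Leu	tRNA	H	2868	2941	TAA
ND1	PCG	H	2942	3916		ATG	TAG
tRNA-Ile	tRNA	H	3923	3993	GAT
tRNA-Gln	tRNA	L	4034	4104	TTG
tRNA-Met	tRNA	H	4123	4193	CAT
ND2	PCG	H	4194	5240		ATG	TAA
tRNA-Trp	tRNA	H	5241	5312	TCA
tRNA-Ala	tRNA	L	5314	5382	TGC
tRNA-Asn	tRNA	L	5385	5457	GTT
tRNA-Cys	tRNA	L	5494	5560	GCA
tRNA-Tyr	tRNA	L	5561	5631	GTA
COXI	PCG	H	5633	7183		GTG	TAA
tRNA-Ser	tRNA	L	7184	7254	TGA
tRNA-Asp	tRNA	H	7284	7354	GTC
COXII	PCG	H	7364	8054		ATG	T
tRNA-Lys	tRNA	H	8055	8128	TTT
ATP8	PCG	H	8130	8297		ATG	TAA
ATP6	PCG	H	8288	8970		ATG	TA
COXIII	PCG	H	8971	9755		ATG	TA
tRNA-Gly	tRNA	H	9756	9825	TCC
ND3	PCG	H	9826	10174		ATG	T
tRNA-Arg	tRNA	H	10175	10243	TCG
ND4L	PCG	H	10244	10540		ATG	TAA
ND4	PCG	H	10534	11914		ATG	T
tRNA-His	tRNA	H	11915	11983	GTG
tRNA-Ser	tRNA	H	11984	12051	GCT
tRNA-Leu	tRNA	H	12057	12129	TAG
ND5	PCG	H	12130	13968		ATG	TAA
ND6	PCG	L	13965	14486		ATG	TAG
tRNA-Glu	tRNA	L	14487	14555	TTC
CYTB	PCG	H	14575	15715		ATG	T
tRNA-Thr	tRNA	H	15716	15787	TGT
tRNA-Pro	tRNA	L	15787	15859	TGG
D-loop	control	H	15860	16871
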
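gene	strand	start	end	size	igs	anticodon	start_codon	stop_codon
tRNA-Ile	H	1	65	65		GAT
tRNA-Gln	L	64	132	69	-2	TTG
tRNA-Met	H	140	205	66	7	CAT
nad2	H	206	1233	1028	0		ATG	TA*
tRNA-Trp	H	1234	1299	66	0	TCA
tRNA-Cys	L	1292	1355	64	-8	GCA
tRNA-Tyr	L	1356	1424	69	0	GTA
cox1	H	1429	2964	1536	4		TTG	TAA
tRNA-Leu(UUR)	H	2967	3032	66	2	TAA
cox2	H	3033	3717	685	0		ATA	T**
tRNA-Lys	H	3718	3787	70	0	CTT
tRNA-Asp	H	3788	3849	62	0	GTC
atp8	H	3850	4008	159	0		ATT	TAA
atp6	H	4002	4682	681	-7		ATG	TAA
cox3	H	4682	5470	789	-1		ATG	TAA
tRNA-Gly	H	5475	5538	64	4	TCC
nad3	H	5536	5892	357	-3		ATA	TAA
tRNA-Ser(AGN)	H	6040	6108	69	147	GCT
tRNA-Ala	H	6283	6347	65	174	TGC
tRNA-Arg	H	6348	6410	63	0	TCG
tRNA-Asn	H	6414	6478	65	3	GTT
tRNA-Glu	H	6541	6604	64	62	TTC
tRNA-Phe	L	6605	6671	67	0	GAA
nad5	L	6672	8400	1729	0		ATG	T**
tRNA-His	L	8401	8464	64	0	GTG
nad4	L	8467	9807	1341	2		ATG	TAA
nad4L	L	9801	10088	288	-7		ATG	TAA
tRNA-Thr	H	10093	10157	65	4	TGT
tRNA-Pro	L	10158	10221	64	0	TGG
nad6	H	10224	10721	498	2		ATT	TAA
cytb	H	10724	11855	1132	2		ATG	T**
tRNA-Ser(UCN)	H	11856	11923	68	0	TGA
nad1	L	11920	12886	967	-4		ATG	T**
tRNA-Leu(CUN)	L	12888	12954	67	1	TAG
16S	L	12955	14237	1283	0
tRNA-Val	L	14238	14305	68	0	TAC
12S	L	14306	15082	777	0
D-loop	H	15083	15322	240	0
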
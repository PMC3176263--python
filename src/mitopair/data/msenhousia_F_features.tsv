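# genome_id: Mse-F
# genome_length: 21557
Type	Name	Starts	Stops	Length	Strand	Anticodon	StartCodon	StopCodon
GENE	nad3	1	390	390	H		ATG	TAA
UR	UR-1	391	625	235				
tRNA	trnY	626	691	66	H	GTA		
UR	UR-2	692	1234	543				
tRNA	trnH	1235	1299	65	H	GTG		
UR	UR-3	1300	1315	16				
tRNA	trnI	1316	1381	66	H	GAT		
UR	UR-4	1382	1391	10				
tRNA	trnN	1392	1457	66	H	GTT		
UR	UR-5	1458	1564	107				
tRNA	trnE	1565	1631	67	H	TTC		
LUR	LUR	1632	6152	4521				
GENE	cox1	6153	7736	1584	H		ATG	TAA
UR	UR-6	7737	8114	378				
GENE	cox2	8115	8774	660	H		ATA	TAA
UR	UR-7	8775	8832	58				
GENE	atp8	8833	8967	135	H		ATG	TAA
UR	UR-8	8968	9051	84	H			
GENE	atp6	9052	9765	714	H		ATG	TAG
UR	UR-9	9766	9791	26				
tRNA	trnT	9792	9858	67	H	TGT		
GENE	cob	9835	11031	1197	H		ATA	TAA
UR	UR-10	11032	11049	18				
tRNA	trnD	11050	11114	65	H	GTC		
UR	UR-11	11115	11123	9				
tRNA	trnR	11124	11189	66	H	TCG		
tRNA	trnS(AGN)	11191	11248	58	H	TCT		
UR	UR-12	11249	11268	20				
tRNA	trnG	11269	11336	68	H	TCC		
rRNA	rrnS	11337	12154	818	H			
GENE	nad6	12155	12778	624	H		ATG	TAA
UR	UR-13	12779	12828	50				
GENE	nad2	12829	13773	945	H		ATA	TAA
UR	UR-14	13774	13855	82				
GENE	cox3	13856	14710	855	H		ATG	TAA
UR	UR-15	14711	14721	11				
tRNA	trnK	14722	14792	71	H	TTT		
UR	UR-16	14793	14797	5				
tRNA	trnF	14798	14865	68	H	GAA		
UR	UR-17	14866	14878	13				
tRNA	trnP	14879	14945	67	H	TGG		
UR	UR-18	14946	14977	32				
tRNA	trnL(CUN)	14978	15042	65	H	TAG		
UR	UR-19	15043	15047	5				
tRNA	trnC	15048	15114	67	H	GCA		
UR	UR-20	15115	15159	45				
tRNA	trnL(UUR)	15160	15223	64	H	TAA		
UR	UR-21	15224	15259	36				
GENE	nad1	15260	16252	993	H		ATG	TAA
UR	UR-22	16253	16385	133				
tRNA	trnM(AUA)	16386	16448	63	H	TAT		
UR	UR-23	16449	16486	38				
tRNA	trnV	16487	16550	64	H	TAC		
UR	UR-24	16551	16695	145				
GENE	nad4L	16696	16911	216	H		ATA	TAA
UR	UR-25	16912	16988	77				
GENE	nad5	16989	18738	1750	H		ATA	T--
tRNA	trnA	18739	18804	66	H	TGC		
UR	UR-26	18805	18843	39				
GENE	nad4	18844	20163	1320	H		ATA	TAG
UR	UR-27	20164	20213	50				
tRNA	trnW	20214	20280	67	H	TCA		
UR	UR-28	20281	20285	5				
tRNA	trnQ	20286	20353	68	H	TTG		
UR	UR-29	20354	20360	7				
tRNA	trnM(AUG)	20361	20427	67	H	CAT		
rRNA	rrnL	20428	21557	1130	H			
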
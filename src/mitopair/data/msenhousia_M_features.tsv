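# genome_id: Mse-M
# genome_length: 20612
Type	Name	Starts	Stops	Length	Strand	Anticodon	StartCodon	StopCodon
GENE	nad3	1	375	375	H		ATG	TAA
UR	UR-1	376	433	58				
tRNA	trnY	434	501	68	H	GTA		
UR	UR-2	502	533	32				
tRNA	trnH	534	599	66	H	GTG		
UR	UR-3	600	618	19				
tRNA	trnI	619	688	70	H	GAT		
tRNA	trnN	687	753	67	H	GTT		
LUR	LUR	754	3597	2844				
tRNA	trnE	3598	3668	71	H	TTC		
UR	UR-4	3669	3708	40				
GENE	cox1	3709	5292	1584	H		ATG	TAA
UR	UR-5	5293	5852	560				
GENE	cox2b	5853	6665	813	H		ATG	TAA
UR	UR-6	6666	6706	41				
GENE	cox2	6707	7396	690	H		ATA	TAA
UR	UR-7	7397	7402	6				
GENE	atp8	7403	7594	192	H		ATG	TAG
UR	UR-8	7595	7612	18				
GENE	atp6	7613	8326	714	H		ATG	TAA
UR	UR-9	8327	8347	21				
tRNA	trnT	8348	8416	69	H	TGT		
GENE	cob	8392	9588	1197	H		ATA	TAA
UR	UR-10	9589	9606	18				
tRNA	trnD	9607	9671	65	H	GTC		
UR	UR-11	9672	9681	10				
tRNA	trnR	9682	9745	64	H	TCG		
tRNA	trnS(AGN)	9747	9806	60	H	TCT		
UR	UR-12	9807	9825	19				
tRNA	trnG	9826	9893	68	H	TCC		
rRNA	rrnS	9894	10793	900	H			
GENE	nad6	10794	11417	624	H		ATG	TAA
UR	UR-13	11418	11472	55				
GENE	nad2	11473	12417	945	H		ATA	TAG
UR	UR-14	12418	12444	27				
GENE	cox3	12445	13299	855	H		ATG	TAG
tRNA	trnK	13299	13366	68	H	TTT		
UR	UR-15	13367	13377	11				
tRNA	trnF	13378	13445	68	H	GAA		
UR	UR-16	13446	13464	19				
tRNA	trnP	13465	13528	64	H	TGG		
UR	UR-17	13529	13554	26				
tRNA	trnL(CUN)	13555	13621	67	H	TAG		
UR	UR-18	13622	13625	4				
tRNA	trnC	13626	13696	71	H	GCA		
UR	UR-19	13697	13737	41				
tRNA	trnL(UUR)	13738	13804	67	H	TAA		
UR	UR-20	13805	13840	36				
GENE	nad1	13841	14836	996	H		ATG	TAG
tRNA	trnM(AUA)	14835	14899	65	H	TAT		
UR	UR-21	14900	14985	86				
tRNA	trnV	14986	15049	64	H	TAC		
UR	UR-22	15050	15183	134				
GENE	nad4L	15184	15399	216	H		ATA	TAA
UR	UR-23	15400	15464	65				
GENE	nad5	15465	17229	1765	H		ATA	T--
tRNA	trnA	17230	17294	65	H	TGC		
UR	UR-24	17295	17338	44				
GENE	nad4	17339	18667	1329	H		ATA	TAA
UR	UR-25	18668	18710	43				
tRNA	trnW	18711	18777	67	H	TCA		
UR	UR-26	18778	18781	4				
tRNA	trnQ	18782	18848	67	H	TTG		
UR	UR-27	18849	18863	15				
tRNA	trnM(AUG)	18864	18930	67	H	CAT		
rRNA	rrnL	18931	20612	1682	H			
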
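# published per-region base composition (percent T, C, A, G on the H strand)
Region	Lineage	Length	pT	pC	pA	pG
UR1-27/LUR	M	4296	37.8	11.2	31.4	19.5
UR1-29/LUR	F	6798	37.9	10.4	30.8	20.9
rrnL	M	1682	37.3	12.6	30.8	19.3
rrnL	F	1130	35.8	13.5	30.4	20.3
rrnS	M	900	36.0	11.6	33.1	19.3
rrnS	F	818	37.2	11.0	32.2	19.7
all rRNA genes	M	2582	36.3	12.2	31.6	19.3
all rRNA genes	F	1948	36.4	12.4	31.2	20.0
atp6	M	714	43.8	12.7	23.5	19.9
atp6	F	714	42.2	12.9	23.8	21.1
atp8	M	192	42.2	14.1	27.6	16.1
atp8	F	135	43.0	12.6	25.9	18.5
cox1	M	1584	38.3	15.9	24.7	21.1
cox1	F	1584	40.0	14.4	24.4	21.3
cox2	M	690	36.7	15.2	26.7	21.4
cox2	F	660	37.4	14.5	27.3	20.8
cox2b	M	813	35.9	14.1	28.7	21.3
cox3	M	855	42.0	13.1	23.3	21.6
cox3	F	855	43.4	12.9	20.9	22.8
cob	M	1197	40.6	13.9	25.2	20.3
cob	F	1197	40.4	13.6	24.9	21.1
nad1	M	996	39.8	12.2	26.0	22.0
nad1	F	993	41.3	11.5	24.4	23.2
nad2	M	945	44.9	10.8	24.4	19.9
nad2	F	945	44.1	10.9	22.4	22.5
nad3	M	375	44.3	14.1	21.3	20.3
nad3	F	390	45.6	12.6	21.0	20.8
nad4	M	1329	41.4	11.5	23.6	23.5
nad4	F	1320	39.9	11.9	24.3	23.9
nad4L	M	216	43.5	8.8	24.5	23.1
nad4L	F	216	44.0	8.8	24.5	22.7
nad5	M	1765	39.5	13.2	27.9	19.4
nad5	F	1750	38.7	13.3	25.7	22.3
nad6	M	624	43.8	11.4	25.6	19.2
nad6	F	624	42.1	12.3	25.2	20.4
all proteins	M	12295	40.6	13.2	25.4	20.9
all proteins	F	11383	40.9	12.8	24.1	22.1
complete	M	20612	39.3	12.7	27.7	20.3
complete	F	21557	39.3	12.0	27.2	21.4
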
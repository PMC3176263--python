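# published per-gene residue counts and F/M divergences (modified NG + JC)
Gene	M_aa	F_aa	pD	SE	Ks	Ka	KaKs
atp6	238	238	0.228	0.026	0.894	0.156	0.17
atp8	64	45	0.302	0.07	0.581	0.233	0.4
cox1	528	528	0.053	0.009	0.838	0.042	0.05
cox2	230	220	0.251	0.027	0.877	0.178	0.2
cox2b	271		0.279	0.029	0.653	0.223	0.35
cox3	285	285	0.155	0.022	0.811	0.107	0.13
cob	399	399	0.058	0.012	0.346	0.034	0.1
nad1	332	331	0.218	0.022	0.67	0.145	0.22
nad2	315	315	0.306	0.026	0.843	0.244	0.29
nad3	125	130	0.218	0.034	0.964	0.162	0.17
nad4	443	440	0.243	0.02	0.931	0.175	0.19
nad4L	72	72	0.183	0.045	0.626	0.107	0.17
nad5	588	583	0.274	0.018	0.862	0.208	0.24
nad6	208	208	0.324	0.031	0.619	0.268	0.43
all proteins	4098	3794			0.716	0.143	0.2
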
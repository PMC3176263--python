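# published codon-usage counts for the F- and M-type M. senhousia mitogenomes
Codon	F	M
UUU	303	333
UUC	36	57
UUA	254	274
UUG	105	104
UCU	107	131
UCC	8	22
UCA	36	36
UCG	14	6
UAU	125	133
UAC	39	36
UAA	14	18
UAG	7	10
UGU	80	90
UGC	14	15
UGA	53	69
UGG	50	46
CUU	89	86
CUC	20	16
CUA	62	55
CUG	41	28
CCU	95	91
CCC	13	14
CCA	11	20
CCG	4	8
CAU	58	51
CAC	15	30
CAA	32	40
CAG	26	22
CGU	35	42
CGC	7	11
CGA	14	12
CGG	13	8
AUU	147	178
AUC	41	43
AUA	139	148
AUG	62	79
ACU	54	61
ACC	9	22
ACA	29	35
ACG	17	12
AAU	82	81
AAC	27	52
AAA	81	104
AAG	33	38
AGU	71	78
AGC	30	43
AGA	90	97
AGG	68	75
GUU	200	193
GUC	24	30
GUA	113	106
GUG	84	83
GCU	88	81
GCC	17	22
GCA	44	44
GCG	22	19
GAU	59	65
GAC	15	22
GAA	44	59
GAG	49	42
GGU	102	103
GGC	39	28
GGA	43	53
GGG	89	88
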
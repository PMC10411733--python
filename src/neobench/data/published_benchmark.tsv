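method	metric	threshold	dop	f1	auc	fpr	fnr	rank_dop	rank_f1	rank_fpr	rank_fnr	ar	ar_sd
DeepHLApan	I	DOP	0,88	0,69	0,57	23,89	28,57	4	5	3	2	3,5	1,29
MHCflurry	B	DOP	0,83	0,67	0,6	36,28	42,86	2	7	7	6	5,5	2,38
PRIME	SI	DOP	0,82	0,7	0,58	53,98	42,86	1	4	12	6	5,75	4,65
DeepHLApan	I	A	0,92	0,65	NA	23,89	28,57	9	10	3	2	6	4,08
DeepImmune	I	DOP	0,95	0,64	0,52	16,81	14,29	12	12	1	1	6,5	6,35
NetMHCpan	R	SB	1,04	0,71	NA	75,22	28,57	14	3	14	2	8,25	6,65
PRIME	RI	DOP	0,84	0,66	0,57	47,79	71,43	3	8	10	13	8,5	4,20
MHCflurry	P	DOP	0,88	0,68	0,53	49,56	71,43	4	6	11	13	8,5	4,20
NetMHCpan	R	WB	1,1	0,77	NA	95,58	28,57	15	1	16	2	8,5	8,10
NetMHCpan	B	DOP	0,88	0,61	0,57	23,01	85,71	4	13	2	16	8,75	6,80
MixMHCpred	S	DOP	0,92	0,61	0,52	34,51	57,14	9	13	6	10	9,5	2,89
MixMHCpred	R	DOP	0,93	0,66	0,54	57,52	42,86	11	8	13	6	9,5	3,11
NetMHCpan	B	WB	1,2	0,74	NA	75,22	42,86	16	2	14	6	9,5	6,61
NetMHCpan	B	SB	1,03	0,65	NA	38,05	57,14	13	10	8	10	10,25	2,06
CIImm	I	DOP	0,9	0,6	0,55	39,82	57,14	7	15	9	10	10,25	3,40
NetMHCpan	R	DOP	0,9	0,59	0,56	33,63	71,43	7	16	5	13	10,25	5,12
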
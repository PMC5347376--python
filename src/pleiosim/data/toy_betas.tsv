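snp	index_trait	maf	height	bmi	sbp	dbp	tg	hdl	ldl	tc	glucose	insulin	homa_b	homa_ir
rs1000	height	0.195	-0.11251	-0.072341	-0.028988	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
rs1001	bmi	0.118	0.0	0.080017	0.056931	0.008297	0.054	0.0	0.0	0.0	0.0	0.0	0.0	0.0
rs1002	sbp	0.417	0.0	0.0	0.129707	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
rs1003	dbp	0.221	0.0	0.0	0.0	-0.080303	-0.023681	0.0	0.0	0.0	0.0	0.0	0.0	0.0
rs1004	tg	0.49	0.0	0.0	0.0	0.0	0.075487	0.034209	0.036796	0.060152	0.0	0.0	0.0	0.0
rs1005	hdl	0.315	0.0	0.0	0.0	0.0	0.0	0.129266	0.069225	0.0	0.0	0.0	0.0	0.0
rs1006	ldl	0.322	0.0	0.0	0.0	0.0	0.0	0.0	-0.148896	-0.031588	0.0	0.0	0.0	0.0
rs1007	tc	0.337	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.111254	0.0	0.0	0.0	0.0
rs1008	glucose	0.354	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.054394	0.025044	0.0	0.0
rs1009	insulin	0.118	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	-0.096621	0.0	0.0
rs1010	homa_b	0.248	0.063462	0.038726	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.141717	0.065173
rs1011	homa_ir	0.158	0.012011	0.02991	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.051179
rs1012	height	0.231	-0.070061	-0.007189	-0.047714	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
rs1013	bmi	0.094	0.0	0.065446	0.018804	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
rs1014	sbp	0.486	0.0	0.0	0.138033	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
rs1015	dbp	0.147	0.0	0.0	0.0	-0.134715	-0.073797	-0.083421	0.0	0.0	0.0	0.0	0.0	0.0
rs1016	tg	0.352	0.0	0.0	0.0	0.0	0.05915	0.0	0.0	0.0	0.0	0.0	0.0	0.0
rs1017	hdl	0.185	0.0	0.0	0.0	0.0	0.0	0.100777	0.071546	0.035563	0.0	0.0	0.0	0.0
rs1018	ldl	0.443	0.0	0.0	0.0	0.0	0.0	0.0	-0.109818	0.0	0.0	0.0	0.0	0.0
rs1019	tc	0.348	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.088763	0.0	0.0	0.0	0.0
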
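code	region	fraction	band	protein
RL_EQ_NL	hippocampus	nuclear	gt10	TRKA
RL_EQ_NL	hippocampus	cytosolic	gt10	ELK
RL_EQ_NL	hippocampus	cytosolic	gt10	pNR2B
RL_EQ_NL	hippocampus	membrane	le10	CDK5
RL_EQ_NL	hippocampus	membrane	gt10	CaNA
RL_EQ_NL	cortex	nuclear	le10	AKT
RL_EQ_NL	cortex	cytosolic	le10	CASP3
RL_EQ_NL	cortex	cytosolic	gt10	TRKA
RL_EQ_NL	cortex	cytosolic	gt10	pPKCAB
RL_EQ_NL	cortex	cytosolic	gt10	pBRAF
RL_EQ_NL	cortex	membrane	le10	CAMKII
BTM_COMP	hippocampus	nuclear	gt10	NUMB
BTM_PLUS_RL	hippocampus	nuclear	le10	pJNK
BTM_PLUS_RL	cortex	nuclear	le10	CaNA
BTM_PLUS_RL	cortex	nuclear	gt10	ERBB4
BTM_PLUS_RL	cortex	nuclear	gt10	ubiquitin
BTM_PLUS_RL	cortex	cytosolic	gt10	GAD2
BTM_PLUS_RL	cortex	membrane	gt10	TIAM1
RL_PLUS_B	hippocampus	nuclear	le10	pEIF4B
RL_PLUS_B	hippocampus	nuclear	le10	TH
RL_PLUS_B	hippocampus	nuclear	gt10	pERK
RL_PLUS_B	hippocampus	cytosolic	gt10	pJNK
RL_PLUS_B	hippocampus	cytosolic	gt10	ERK
RL_PLUS_B	hippocampus	membrane	le10	NR2B
RL_PLUS_B	cortex	cytosolic	le10	AKT
RL_PLUS_B	cortex	cytosolic	gt10	CTNNB1
RL_PLUS_B	cortex	cytosolic	gt10	RSK
RL_PLUS_B	cortex	cytosolic	gt10	RCAN1
RL_PLUS_B	cortex	cytosolic	gt10	MTOR
RL_PLUS_B	cortex	membrane	le10	SYP
RL_PLUS_B_PLUS_BTM	hippocampus	nuclear	le10	Ubiquitin
RL_PLUS_B_PLUS_BTM	hippocampus	nuclear	gt10	SOD1
RL_PLUS_B_PLUS_BTM	hippocampus	nuclear	gt10	ERBB4
RL_PLUS_B_PLUS_BTM	hippocampus	nuclear	gt10	PP2A
RL_PLUS_B_PLUS_BTM	hippocampus	cytosolic	le10	JNK
RL_PLUS_B_PLUS_BTM	hippocampus	cytosolic	le10	pP70S6
RL_PLUS_B_PLUS_BTM	hippocampus	cytosolic	gt10	IL1B
RL_PLUS_B_PLUS_BTM	cortex	nuclear	le10	ARC
RL_PLUS_B_PLUS_BTM	cortex	nuclear	le10	pS6
RL_PLUS_B_PLUS_BTM	cortex	nuclear	gt10	pPKCAB
RL_PLUS_B_PLUS_BTM	cortex	nuclear	gt10	IL1B
RL_PLUS_B_PLUS_BTM	cortex	nuclear	gt10	pGSK3BS9
RL_PLUS_B_PLUS_BTM	cortex	nuclear	gt10	SNCA
RL_PLUS_B_PLUS_BTM	cortex	cytosolic	le10	pMEK
RL_PLUS_B_PLUS_BTM	cortex	cytosolic	le10	RAPTOR
RL_PLUS_B_PLUS_BTM	cortex	cytosolic	le10	pNR2A
RL_PLUS_B_PLUS_BTM	cortex	cytosolic	gt10	pNUMB
RL_PLUS_B_PLUS_BTM	cortex	cytosolic	gt10	IL1B
RL_PLUS_B_PLUS_BTM	cortex	cytosolic	gt10	S6
RL_PLUS_B_PLUS_BTM	cortex	cytosolic	gt10	pGSK3B-T216
RL_PLUS_B_PLUS_BTM	cortex	cytosolic	gt10	pCASP9
RL_PLUS_B_PLUS_BTM	cortex	cytosolic	gt10	Ubiquitin
RL_PLUS_B_PLUS_BTM	cortex	cytosolic	gt10	pERK
RL_PLUS_B_PLUS_BTM	cortex	cytosolic	gt10	P70S6
RL_PLUS_B_PLUS_BTM	cortex	cytosolic	gt10	BAX
RL_PLUS_B_PLUS_BTM	cortex	cytosolic	gt10	TAU
RL_PLUS_B_PLUS_BTM	cortex	membrane	gt10	pERK
RL_PLUS_B_PLUS_BTM	cortex	membrane	gt10	TRKA
RL_PLUS_B_PLUS_BTM	cortex	membrane	gt10	pNUMB
RL_PLUS_B_PLUS_BTM	cortex	membrane	gt10	CTNNB1
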
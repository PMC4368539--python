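code	region	fraction	band	protein
FL_EQ_NL	hippocampus	nuclear	le10	CaNA
FL_EQ_NL	hippocampus	nuclear	le10	H3AcK9
FL_EQ_NL	hippocampus	nuclear	gt10	pSRC
FL_EQ_NL	hippocampus	cytosolic	le10	RAPTOR
FL_EQ_NL	hippocampus	cytosolic	le10	BAD
FL_EQ_NL	hippocampus	cytosolic	gt10	CDK5
FL_EQ_NL	hippocampus	cytosolic	gt10	EGR1
FL_EQ_NL	hippocampus	cytosolic	gt10	pERK
FL_EQ_NL	hippocampus	cytosolic	gt10	MTOR
FL_EQ_NL	hippocampus	cytosolic	gt10	pNR1
FL_EQ_NL	hippocampus	cytosolic	gt10	pNR2A
FL_EQ_NL	hippocampus	membrane	le10	NR1
FL_EQ_NL	hippocampus	membrane	le10	pNR1
FL_EQ_NL	hippocampus	membrane	gt10	RCAN1
FL_EQ_NL	cortex	nuclear	le10	EGR1
FL_EQ_NL	cortex	nuclear	le10	H3MeK4
FL_EQ_NL	cortex	nuclear	le10	nNOS
FL_EQ_NL	cortex	nuclear	le10	SOD1
FL_EQ_NL	cortex	nuclear	gt10	BRAF
FL_EQ_NL	cortex	nuclear	gt10	pERK
FL_EQ_NL	cortex	nuclear	gt10	P38
FL_EQ_NL	cortex	cytosolic	gt10	BDNF
FL_EQ_NL	cortex	membrane	le10	FYN
FL_EQ_NL	cortex	membrane	gt10	pCAMKII
B_COMP	hippocampus	nuclear	le10	JNK
B_COMP	hippocampus	nuclear	le10	pAKT
B_COMP	hippocampus	nuclear	le10	pGSK3BS9
B_COMP	hippocampus	nuclear	le10	pMEK
B_COMP	hippocampus	nuclear	le10	pPKCAB
B_COMP	hippocampus	nuclear	le10	RSK
B_COMP	hippocampus	nuclear	gt10	ELK
B_COMP	hippocampus	nuclear	gt10	P70S6
B_COMP	hippocampus	nuclear	gt10	PKCA
B_COMP	hippocampus	nuclear	gt10	pCFOS
B_COMP	hippocampus	nuclear	gt10	pMTOR
B_COMP	hippocampus	nuclear	gt10	pRSK
B_COMP	hippocampus	cytosolic	gt10	AKT
B_COMP	hippocampus	cytosolic	gt10	P70S6
B_COMP	hippocampus	membrane	gt10	BDNF
B_COMP	cortex	nuclear	gt10	CDK5
B_COMP	cortex	nuclear	gt10	pNUMB
B_COMP	cortex	cytosolic	le10	pAKT
B_COMP	cortex	cytosolic	le10	pNR1
B_COMP	cortex	cytosolic	le10	pRSK
B_COMP	cortex	cytosolic	gt10	ELK
B_COMP	cortex	cytosolic	gt10	JNK
B_COMP	cortex	cytosolic	gt10	TIAM1
B_COMP	cortex	membrane	le10	pGluR2
B_PLUS_FL	hippocampus	nuclear	le10	BRAF
B_PLUS_FL	hippocampus	nuclear	le10	FYN
B_PLUS_FL	hippocampus	nuclear	gt10	H3AcK18
B_PLUS_FL	hippocampus	nuclear	gt10	GSK3B
B_PLUS_FL	hippocampus	cytosolic	le10	NR2B
B_PLUS_FL	hippocampus	cytosolic	le10	pBRAF
B_PLUS_FL	hippocampus	cytosolic	le10	pMTOR
B_PLUS_FL	hippocampus	cytosolic	gt10	pMEK
B_PLUS_FL	hippocampus	membrane	le10	NR2A
B_PLUS_FL	hippocampus	membrane	gt10	pERK
B_PLUS_FL	cortex	nuclear	le10	DYRK1A
B_PLUS_FL	cortex	nuclear	le10	ITSN1
B_PLUS_FL	cortex	cytosolic	le10	P70S6
B_PLUS_FL	cortex	cytosolic	gt10	NR2B
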
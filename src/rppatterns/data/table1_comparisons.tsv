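code	group_a	group_b	interpretation
B	t-SC-sal	c-SC-sal	initial genotype differences
B-tm	t-SC-mem	t-SC-sal	memantine effect on trisomic baseline
B-cm	c-SC-mem	c-SC-sal	memantine effect on control baseline
B-tm-cs	t-SC-mem	c-SC-sal	memantine effect on genotype differences
NL	c-CS-sal	c-SC-sal	training effect in saline controls (normal learning)
FL	t-CS-sal	t-SC-sal	training effect in saline trisomics (failed learning)
RL	t-CS-mem	t-SC-mem	training effect in memantine trisomics (rescued learning)
RL-FL	t-CS-mem	t-CS-sal	rescued vs failed final profiles
RL-NL	t-CS-mem	c-CS-sal	rescued vs normal final profiles
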
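region	fraction	comparison	n_up	n_down
hippocampus	nuclear	NL	36	3
hippocampus	nuclear	FL	6	20
hippocampus	nuclear	B	41	0
hippocampus	nuclear	RL	6	20
hippocampus	nuclear	B-tm	17	2
hippocampus	nuclear	B-tm-cs	50	0
hippocampus	nuclear	RL-FL	22	0
hippocampus	nuclear	RL-NL	5	2
hippocampus	cytosolic	NL	23	14
hippocampus	cytosolic	FL	21	11
hippocampus	cytosolic	B	20	3
hippocampus	cytosolic	RL	23	2
hippocampus	cytosolic	B-tm	7	10
hippocampus	cytosolic	B-tm-cs	21	5
hippocampus	cytosolic	RL-FL	3	5
hippocampus	cytosolic	RL-NL	11	4
hippocampus	membrane	NL	8	6
hippocampus	membrane	FL	3	9
hippocampus	membrane	B	6	2
hippocampus	membrane	RL	6	7
hippocampus	membrane	B-tm	4	5
hippocampus	membrane	B-tm-cs	9	5
hippocampus	membrane	RL-FL	7	0
hippocampus	membrane	RL-NL	3	0
cortex	nuclear	NL	14	13
cortex	nuclear	FL	7	20
cortex	nuclear	B	20	5
cortex	nuclear	RL	9	38
cortex	nuclear	B-tm	14	8
cortex	nuclear	B-tm-cs	19	0
cortex	nuclear	RL-FL	2	10
cortex	nuclear	RL-NL	2	13
cortex	cytosolic	NL	25	13
cortex	cytosolic	FL	6	10
cortex	cytosolic	B	30	12
cortex	cytosolic	RL	19	19
cortex	cytosolic	B-tm	15	12
cortex	cytosolic	B-tm-cs	28	3
cortex	cytosolic	RL-FL	7	4
cortex	cytosolic	RL-NL	10	4
cortex	membrane	NL	3	12
cortex	membrane	FL	4	7
cortex	membrane	B	6	12
cortex	membrane	RL	2	20
cortex	membrane	B-tm	19	4
cortex	membrane	B-tm-cs	16	0
cortex	membrane	RL-FL	3	6
cortex	membrane	RL-NL	3	1
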
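block	level	n	wild_type	mutation
T stage	T1	0	0	0
T stage	T2	9	9	0
T stage	T3	63	58	5
T stage	T4	35	32	3
N stage	N0	37	35	2
N stage	N1	41	38	3
N stage	N2	29	26	3
M stage	M0	54	53	1
M stage	M1	53	46	7
AJCC stage	I	6	6	0
AJCC stage	II	13	12	1
AJCC stage	III	32	32	0
AJCC stage	IV	56	49	7
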
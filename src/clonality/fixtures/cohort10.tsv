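patient	cluster	n_mutations	ccf_primary	ccf_met
P1	c0	55	1.00	1.00
P1	c1	22	0.55	0.85
P1	c2	14	0.40	0.70
P2	c0	48	1.00	1.00
P2	c1	25	0.55	0.45
P2	c2	18	0.30	0.40
P3	c0	60	1.00	1.00
P3	c1	20	0.50	0.55
P3	c2	16	0.35	0.30
P3	c3	10	0.25	0.02
P4	c0	42	1.00	1.00
P4	c1	23	0.60	0.90
P4	c2	12	0.45	0.75
P4	c3	9	0.30	0.02
P5	c0	51	1.00	1.00
P5	c1	19	0.45	0.50
P5	c2	15	0.40	0.35
P6	c0	46	1.00	1.00
P6	c1	27	0.60	0.40
P6	c2	13	0.25	0.45
P6	c3	8	0.10	0.10
P7	c0	57	1.00	1.00
P7	c1	21	0.50	0.30
P7	c2	17	0.35	0.55
P8	c0	49	1.00	1.00
P8	c1	16	0.45	0.02
P8	c2	11	0.30	0.02
P9	c0	53	1.00	1.00
P9	c1	24	0.55	0.35
P9	c2	14	0.30	0.50
P9	c3	9	0.20	0.25
P10	c0	44	1.00	1.00
P10	c1	26	0.65	0.88
P10	c2	15	0.50	0.72
P10	c3	10	0.35	0.60
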
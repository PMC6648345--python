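1	1_TssA	a
2	2_TssAFlnk	b
3	3_TxFlnk	c
4	4_Tx	d
5	5_TxWk	e
6	6_EnhG	f
7	7_Enh	g
8	8_ZNF/Rpts	h
9	9_Het	i
10	10_TssBiv	j
11	11_BivFlnk	k
12	12_EnhBiv	l
13	13_ReprPC	m
14	14_ReprPCWk	n
15	15_Quies	o
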
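node	snp_id	ancestral	derived
E-M96	M96	G	C
E1b-V13	V13	G	A
E2-M75	M75	G	A
F-M89	M89	C	T
G-M201	M201	G	T
G1-M342	M342	C	T
G2a-P15	P15	C	T
IJ-M429	M429	T	A
I-M170	M170	A	C
I1-M253	M253	C	T
I2-M438	M438	A	G
J-M304	M304	A	C
J1-M267	M267	T	G
J2-M172	M172	T	G
K-M9	M9	C	G
P-M45	M45	G	A
R1a-M420	M420	A	C
R1b-M343	M343	C	A
R1b1-L21	L21	C	G
R1b1-L21	DF13	C	T
R1b2-U106	U106	C	T
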
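# Published candidate consensus mutations for the PM1 laccase (OB-1 variant):
# per-mutation relative entropy (nats), per-position mutual information (nats),
# and the consensus/ancestor residue pair as printed (first/second member kept
# verbatim; the orientation of the pair is not resolved here).
mutation	re	mi	consensus	ancestor
I25V	1.80	0.54	V	V
V27A	1.43	0.47	V	A
S33G	2.37	0.22	G	G
D50N	1.28	0.34	N	N
M52L	2.12	0.14	L	L
A92S	1.70	0.42	S	S
D142E	1.26	0.42	E	E
T179G	1.59	0.53	G	G
Y208F	1.17	0.42	F	F
L217M	1.58	0.42	M	M
V219I	1.26	0.28	I	I
Q230L	0.85	0.51	L	L
A240G	1.47	0.27	G	G
D250N	1.59	0.42	N	N
N268G	1.40	0.58	G	N
T306P	2.40	0.30	P	P
M327L	1.47	0.43	L	L
Y421R	1.59	0.59	R	R
F454W	2.40	0.34	W	W
M464F	1.30	0.29	F	F
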
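# Synthetic cathepsin-B-like subsite preference matrix (not a database export). L1-minimal perturbation of a dibasic P1/P2, Gly-tolerant-P1' prior under the constraint that the top-3 bonds of the four study constructs match their published fragment sets (margin 0.5). Arbitrary additive score units.
subsite	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
P4	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.81	0.0	0.0	0.15	-0.19	0.0	0.0	0.0	0.0	0.0	0.0	0.0
P3	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.08	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
P2	0.0	0.0	0.0	0.0	1.0	0.0	0.0	0.0	0.46	1.0	0.0	0.92	0.88	0.0	2.0	0.0	0.0	0.0	0.0	0.0
P1	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.58	0.0	0.0	0.27	0.0	0.0	2.0	0.0	0.0	0.0	0.0	0.0
P1'	0.5	0.0	0.0	0.0	0.0	1.0	0.0	0.0	-0.23	0.54	0.0	0.0	0.0	-0.12	0.0	0.5	0.0	0.0	0.0	0.0
P2'	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	-0.58	0.0	0.0	0.0	0.0	0.0
P3'	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
P4'	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.73	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
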
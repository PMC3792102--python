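# name: pnp_glu_kcat
# objective: KCAT
rank	energy	162	163	164	355	356	361	362	549	550
WT	-129.7	H	D	F	V	G	L	G	W	N
1	-380.6	G	D	Q	A	G	R	D	A	A
2	-375.1	G	D	Q	A	G	K	D	A	A
3	-374.5	Q	D	Q	A	G	G	R	A	A
4	-361.0	G	D	Q	A	G	E	K	A	A
5	-355.5	N	D	Q	V	G	S	G	A	A
6	-349.3	C	D	Q	V	G	S	G	A	A
7	-346.7	G	K	Q	E	G	S	R	A	A
8	-341.3	G	K	Q	A	G	A	K	A	A
9	-340.8	Q	D	Q	A	G	G	K	A	A
10	-336.1	L	D	Q	A	G	G	K	A	A
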
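# name: pnp_gal_kcat
# objective: KCAT
rank	energy	162	163	164	355	356	361	362	549	550
WT	25.4	H	D	F	V	G	L	G	W	N
1	-251.9	G	D	Q	A	G	E	K	A	A
2	-245.3	A	D	Q	A	G	G	R	T	A
3	-244.2	A	D	Q	A	G	G	A	T	A
4	-240.0	A	D	Q	A	G	G	K	T	A
5	-234.2	A	D	Q	A	G	E	K	A	A
6	-233.7	S	D	Q	A	G	D	K	A	G
7	-232.7	A	D	Q	A	G	G	K	K	S
8	-232.5	A	D	M	A	G	G	S	R	S
9	-227.9	G	D	Q	A	G	E	K	R	S
10	-220.3	S	D	Q	A	G	S	G	K	S
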
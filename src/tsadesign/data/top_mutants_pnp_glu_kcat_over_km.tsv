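# name: pnp_glu_kcat_over_km
# objective: KCAT_OVER_KM
rank	energy	162	163	164	355	356	361	362	549	550
WT	-377.8	H	D	F	V	G	L	G	W	N
1	-1570.6	N	D	Q	A	G	G	D	A	A
2	-1561.4	N	D	Q	A	G	G	K	A	A
3	-1560.2	A	D	Q	A	G	G	K	A	A
4	-1551.4	G	K	Q	A	G	S	K	A	A
5	-1531.3	A	R	Q	A	G	S	G	A	A
6	-1520.8	Q	D	Q	A	G	G	D	A	A
7	-1518.3	A	D	Q	A	G	K	D	A	G
8	-1514.2	A	D	Q	A	G	G	D	A	A
9	-1502.9	S	D	Q	A	G	G	S	A	A
10	-1495.3	S	S	Q	E	G	K	G	A	A
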
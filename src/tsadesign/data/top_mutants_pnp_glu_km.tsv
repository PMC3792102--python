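# name: pnp_glu_km
# objective: KM
rank	energy	162	163	164	355	356	361	362	549	550
WT	-489.4	H	D	F	V	G	L	G	W	N
1	-1548.7	Q	D	Q	A	A	G	D	R	G
2	-1513.6	A	D	Q	A	G	G	R	R	A
3	-1509.8	G	S	Q	A	G	K	D	A	S
4	-1482.6	Q	D	Q	A	A	G	D	A	G
5	-1477.6	A	S	Q	A	G	G	D	A	A
6	-1455.9	S	S	Q	A	A	G	D	A	G
7	-1454.6	A	S	F	A	A	G	D	A	G
8	-1440.0	A	S	Q	A	G	G	R	A	S
9	-1434.1	S	D	Q	A	G	G	R	R	A
10	-1429.9	A	S	Q	C	G	K	D	A	G
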
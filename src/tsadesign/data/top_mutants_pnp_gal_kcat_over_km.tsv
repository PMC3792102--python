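# name: pnp_gal_kcat_over_km
# objective: KCAT_OVER_KM
rank	energy	162	163	164	355	356	361	362	549	550
WT	90.1	H	D	F	V	G	L	G	W	N
1	-1041.2	A	D	Q	A	G	R	G	R	S
2	-1034.9	Q	D	Q	A	G	K	D	R	G
3	-1004.4	S	D	Q	A	G	G	S	R	S
4	-975.1	A	D	Q	A	G	G	S	R	S
5	-969.7	N	D	Q	A	G	G	D	K	S
6	-956.7	N	D	Q	A	G	G	D	R	S
7	-940.8	S	D	Q	A	G	G	K	R	S
8	-931.2	Q	D	Q	A	G	D	K	A	G
9	-930.3	A	D	Q	A	G	G	D	K	S
10	-924.9	A	D	Q	A	G	G	K	K	S
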
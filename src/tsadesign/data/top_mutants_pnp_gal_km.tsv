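# name: pnp_gal_km
# objective: KM
rank	energy	162	163	164	355	356	361	362	549	550
WT	-70.7	H	D	F	V	G	L	G	W	N
1	-1528.8	S	D	Q	A	G	G	K	A	A
2	-1514.2	S	D	Q	A	G	N	G	R	S
3	-1505.0	S	K	Q	A	G	E	K	A	G
4	-1472.3	A	K	Q	A	A	S	G	A	G
5	-1453.1	N	D	Q	A	G	N	G	R	S
6	-1442.6	S	S	Q	A	G	A	G	A	A
7	-1435.5	S	D	Q	A	G	D	K	K	G
8	-1423.8	S	S	Q	A	G	G	D	A	A
9	-1413.7	S	D	Q	A	G	N	G	K	S
10	-1408.7	G	K	Q	E	G	A	A	A	A
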
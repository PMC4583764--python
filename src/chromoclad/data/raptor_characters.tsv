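# Binary chromosomal rearrangement characters for the diurnal birds of prey
# (13 OTUs x 59 presence/absence characters; chicken GGA is the outgroup).
# Labels name the GGA chromosomes/segments joined (association) or split
# (disruption); 'mic' = microchromosome, 'prx/med/dis' = proximal/medial/distal.
# OTUs pooling species with identical painting patterns: GCA (+CAU),
# GFU (+GHI, GRU), BNI (+BME, RMA).
# Note: published per-species tallies for BBU (fourteen disruptions + ten
# associations) exceed the 22 derived states of the BBU column; states here
# follow the printed matrix, which matches the shared-character lists.
#taxa	GGA	FTI	FPE	FCO	GCA	PHA	GBA	GFU	HHA	NNI	BNI	PAL	BBU
#members	GCA=GCA,CAU	GFU=GFU,GHI,GRU	BNI=BNI,BME,RMA
#outgroup	GGA
index	label	rclass	states	notes
1	1p/1q	disruption	0110011111111	
2	2p/2q	disruption	0111011111111	
3	3qprx/3qmed	disruption	0000011111111	grouped in print with 18, 20, 21, 27, 28 as uniting the osprey with Accipitridae; that list names seven characters but six indices (31 shares the identical pattern and is the likely seventh)
4	5qprx/5qdis	disruption	0111011111111	
5	5qprx/mic1	association	0111011101111	derived state absent only from GGA, GCA and HHA; minimal reading is a basal gain with a reversal in HHA
6	2p/mic2	association	0111000000000	
7	2q/mic3	association	0111000000000	
8	4p/mic4	association	0111000000000	
9	4q/mic5	association	0111000000000	
10	5qmed/mic6	association	0111000000000	
11	6/mic7	association	0111000000000	
12	7/mic8	association	0111000000000	
13	(5qdis + mic6)/(7 + mic8)	association	0011000000000	
14	3qdis-1/(4q + mic5)	association	0001000000000	
15	3qprx-1/(2p + mic2)	association	0001000000000	
16	(2q + mic3)/(5qprx + mic1)	association	0001000000000	
17	8/(6 + mic7)	association	0001000000000	
18	1pdis/1pmed	disruption	0000010111111	state 0 in GBA alone within the osprey+accipitrid assemblage; convergence versus reversal is undecidable across the equally parsimonious trees
19	1pmed/1pprx	disruption	0000010101001	
20	1qprx/1qmed	disruption	0000011111111	
21	1qmed/1qdis	disruption	0000011111111	
22	1qdis-a/1qdis-b	disruption	0000010111001	interpretation unstable across the equally parsimonious trees (branching of GBA and/or HHA)
23	1pdis-a/1pdis-b	disruption	0000000000001	BBU-specific further fission of the GGA 1pter segment
24	1seg-n1/mic9	association	0000000010000	
25	1seg-n2/mic10	association	0000000010000	
26	(1seg-n1 + mic9)/(1seg-n2 + mic10)	association	0000000010000	
27	3qmed-1/3qmed-2	disruption	0000011111111	
28	3qmed-2/3qdis	disruption	0000011111111	
29	3qprx/mic11	association	0000011101001	
30	3qmed-1/mic12	association	0000010101001	
31	7/mic13	association	0000011111111	pattern identical to characters 3, 20, 21, 27, 28 (osprey + Accipitridae)
32	8/mic14	association	0000010101001	
33	2qprx/mic15	association	0000001101001	convergence versus reversal undecidable across the equally parsimonious trees
34	2p/mic16	association	0000000010000	
35	6qprx/6qdis	disruption	0000010000000	
36	1seg-na/9	association	0000010000000	
37	1seg-nb/4p	association	0000010000000	
38	1seg-nc/6qprx	association	0000010000000	
39	1seg-nd/mic16	association	0000010000000	
40	1seg-ne/mic17	association	0000010000000	
41	9/mic18	association	0000001111001	interpretation unstable across the equally parsimonious trees (branching of GBA and/or HHA)
42	2qprx/2qdis	disruption	0000001101111	a fission (2qprx/2qdis) that published per-species summaries group with the associations shared by the 2n=66 Old World vultures and BBU; kept as a disruption here; interpretation unstable across the equally parsimonious trees
43	2qdis-a/2qdis-b	disruption	0000001000000	
44	1seg-nA/1seg-nB	association	0000001000000	
45	1seg-nC/3qmed-1	association	0000001000000	
46	6/mic-NOR	association	0000000010000	
47	(3q-n + mic19)/5 dis	association	0000000010000	
48	6/mic20	association	0000001001000	convergence versus reversal undecidable across the equally parsimonious trees
49	1pdis/6	association	0000000000110	
50	mic21-a/mic21-b	disruption	0000000000001	BBU-specific fission of a microchromosome segment
51	1pdis-2/6	association	0000000000001	BBU-specific fusion of the GGA 1pdis-2 segment with GGA 6
52	2p/mic22	association	0000010000000	
53	2qprx/mic23	association	0000000001000	
54	3qprx-1/3qdis-1	disruption	0111000000000	
55	3qmed-2/mic24	association	0000000001000	
56	3q-n/mic25	association	0000000010000	
57	5qdis/mic26	association	0000010000000	
58	6qdis/mic27	association	0000010000000	
59	4p/4q	disruption	1000000000000	derived in the outgroup GGA only (the fused state of chicken chromosome 4); polarized as a loss along the ingroup stem
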
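# Chromosome-painting homology maps: chromosomes/segments homologous to
# chicken (GGA) chromosomes 1-5 in the stone curlew (BOE) and the diurnal
# birds of prey. A label containing '+' (e.g. '8p + q') is ONE fused target
# chromosome. 'pooled_with' lists species published jointly with the row
# species (identical painting patterns). Two GFU rows exist: an earlier
# literature map (shared with GRU) and the present-study map (shared with
# GHI); the present-study row is the default for GFU.
# NNI GGA3: the printed row splits across lines; '17, 20' is assigned to
# GGA3 (the character matrix implies >= 4 GGA3 segments in NNI).
species	pooled_with	2n	source	GGA1	GGA2	GGA3	GGA4	GGA5
BOE		42	literature	1	2	3	4, 8p	6
GCA		80	literature	1	2	3	4, 9	5
CAU		80	literature	1	2	3	4, 9	5
HHA		58	literature	5, 6, 19, 21, 24	1, 3	2p, 10, 18, 23	4, 14	2q, 20
PAL		66	literature	3p + q, 6, 7, 15, 18	2, 4, 20	9, 13, 17, 26	1, 16	5, 14q
BME	BNI,RMA	68	literature	3p + q, 6, 7, 15, 18	2, 4, 20	9, 13, 17, 26	1, 16	5, 14q
GBA		60	literature	7, 8p, 11, 12q	1q, 2, 14q, 23q	8q, 13, 21q, 22q	3, 16	15q, 20
GFU	GRU	66	literature	7, 12, 15, 19, 20, 22	2, 3, 23	8, 16q, 21, 24	1, 13	14q, 17
NNI		66	literature	6, 13, 15, 19, 21, 24, 28	2, 3, 22	10, 12, 17, 20	1, 14	11, 16
GFU	GHI	66	present_study	7, 12, 21, 22, 23, 26, 28	2, 3, 24	8p + q, 16q, 19, 25	1, 13	11q, 17
BBU		68	present_study	6q, 7, 12, 21, 22, 23, 26, 27	2, 3, 24	8p + q, 16q, 19, 25	1, 13	11q, 17
PHA		74	literature	1q, 2q, 3p, 4q, 5p, 23, 24	9q, 17	6q, 11q, 13q, 21	4p, 8, 18	15q, 19
FCO		40	literature	2	3q, 4q	1p, 4p	1q, 8	3p, 5q
FPE		50	literature	4, 6	3, 5	7, 11	2, 13	1p, 9
FTI		52	literature	3, 5	2, 4	6, 12	1, 14	7, 10
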
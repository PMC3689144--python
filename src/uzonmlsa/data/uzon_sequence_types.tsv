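# Sequence types of the 106 Thermoanaerobacter uzonensis isolates from the
# Uzon Caldera (Kamchatka) MLSA survey: allelic profile over eight
# protein-coding loci, with isolate counts per (hot spring, sampling year).
# year 0 = sampling year not resolved by the published summary (the ST was
# recovered from the same spring in both 2005 and 2006 and the per-year
# split is not recorded).
st	gyrB	lepA	leuS	pyrG	recA	recG	rplB	rpoB	spring	year	n_isolates
1	1	1	2	2	1	2	2	1	Arkashin	2006	1
2	1	1	1	3	1	3	3	2	Arkashin	2006	1
3	1	1	3	4	1	2	1	1	Arkashin	2006	1
4	1	1	4	4	1	2	3	2	Arkashin	2006	1
5	1	1	5	6	1	4	2	4	Burlyashi	2006	1
6	1	1	6	7	3	5	4	2	Burlyashi	2006	1
7	1	1	1	8	1	3	3	3	Burlyashi	2006	1
8	1	1	5	9	1	2	3	3	Burlyashi	2006	1
9	3	2	5	10	1	6	3	5	Burlyashi	2006	1
10	1	1	5	4	1	3	3	2	Burlyashi	2006	1
11	1	3	5	11	1	4	2	6	Burlyashi	2006	1
12	1	1	5	5	2	2	3	3	Burlyashi	2006	3
13	3	1	1	12	1	2	3	3	Burlyashi	2006	1
14	1	4	1	13	1	7	3	3	Burlyashi	2006	1
15	2	1	7	10	4	4	3	3	Burlyashi	2006	1
16	2	1	4	6	1	2	3	3	Burlyashi	2006	3
17	1	1	8	6	4	4	3	3	Burlyashi	2006	1
18	1	4	1	14	1	7	3	3	Burlyashi	2006	1
19	1	5	9	17	1	8	3	3	Thermophilny	2006	1
20	1	1	10	18	1	3	2	2	Thermophilny	2006	1
21	1	1	1	19	5	9	3	2	Thermophilny	2006	1
22	1	4	5	20	1	2	3	3	Thermophilny	2006	1
23	1	1	1	1	1	1	1	1	Arkashin	2005	8
23	1	1	1	1	1	1	1	1	Arkashin	2006	3
24	4	1	9	3	1	10	2	2	Pulsating	2006	3
25	4	7	9	3	1	10	2	2	Pulsating	2006	1
26	3	6	5	10	1	2	3	5	Pulsating	2006	3
27	1	8	5	10	1	11	1	7	ON1	2006	1
28	1	7	1	21	1	12	3	8	ON1	2006	1
29	1	1	1	21	1	9	3	8	ON1	2006	1
30	1	7	1	21	1	9	3	8	ON1	2006	1
31	1	8	5	10	1	11	1	3	ON1	2006	3
32	3	7	5	10	1	3	2	2	ON1	2006	1
33	1	4	5	10	1	11	1	3	ON1	2006	4
34	4	1	1	22	6	13	3	3	Thermophilny	2005	1
35	4	7	1	22	1	13	3	3	Thermophilny	2005	1
36	1	1	8	15	4	4	3	3	Thermophilny	0	11
37	1	9	5	23	1	2	3	3	Thermophilny	2005	1
38	1	1	9	16	1	5	3	3	Thermophilny	0	7
39	1	10	5	23	1	2	3	3	Thermophilny	2005	1
40	4	4	9	3	1	6	2	2	Vent1North	2006	1
41	1	12	1	25	1	11	3	3	Vent1North	2006	2
42	1	13	5	24	1	3	3	3	Vent1North	2006	1
43	1	11	1	25	1	11	3	3	Vent1North	2006	8
44	1	1	5	24	1	3	3	3	Vent1North	2006	6
45	1	1	5	4	7	2	3	2	Zavarzin	2006	1
46	1	4	1	4	1	15	3	3	Zavarzin	2006	1
47	3	1	5	4	7	2	2	6	Zavarzin	2006	2
48	1	11	9	11	1	16	2	2	Zavarzin	2006	1
49	1	4	1	4	1	14	3	3	Zavarzin	2006	5
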
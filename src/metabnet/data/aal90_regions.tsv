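index	abbreviation	name	hemisphere	func_class	provenance
1	PreCG	Precentral gyrus	L	paralimbic	reported
2	PreCG	Precentral gyrus	R	paralimbic	mirrored
3	SFGdor	Superior frontal gyrus, dorsolateral	L	association	assigned
4	SFGdor	Superior frontal gyrus, dorsolateral	R	association	assigned
5	ORBsup	Superior frontal gyrus, orbital part	L	paralimbic	assigned
6	ORBsup	Superior frontal gyrus, orbital part	R	paralimbic	assigned
7	MFG	Middle frontal gyrus	L	association	reported
8	MFG	Middle frontal gyrus	R	association	reported
9	ORBmid	Middle frontal gyrus, orbital part	L	paralimbic	reported
10	ORBmid	Middle frontal gyrus, orbital part	R	paralimbic	mirrored
11	IFGoperc	Inferior frontal gyrus, opercular part	L	association	assigned
12	IFGoperc	Inferior frontal gyrus, opercular part	R	association	assigned
13	IFGtriang	Inferior frontal gyrus, triangular part	L	association	reported
14	IFGtriang	Inferior frontal gyrus, triangular part	R	association	mirrored
15	ORBinf	Inferior frontal gyrus, orbital part	L	paralimbic	assigned
16	ORBinf	Inferior frontal gyrus, orbital part	R	paralimbic	assigned
17	ROL	Rolandic operculum	L	association	assigned
18	ROL	Rolandic operculum	R	association	assigned
19	SMA	Supplementary motor area	L	association	mirrored
20	SMA	Supplementary motor area	R	association	reported
21	OLF	Olfactory cortex	L	paralimbic	reported
22	OLF	Olfactory cortex	R	paralimbic	reported
23	SFGmed	Superior frontal gyrus, medial	L	association	assigned
24	SFGmed	Superior frontal gyrus, medial	R	association	assigned
25	ORBsupmed	Superior frontal gyrus, medial orbital	L	paralimbic	reported
26	ORBsupmed	Superior frontal gyrus, medial orbital	R	paralimbic	mirrored
27	REC	Gyrus rectus	L	association	reported
28	REC	Gyrus rectus	R	association	reported
29	INS	Insula	L	paralimbic	reported
30	INS	Insula	R	paralimbic	reported
31	ACG	Anterior cingulate and paracingulate gyri	L	paralimbic	assigned
32	ACG	Anterior cingulate and paracingulate gyri	R	paralimbic	assigned
33	DCG	Median cingulate and paracingulate gyri	L	paralimbic	assigned
34	DCG	Median cingulate and paracingulate gyri	R	paralimbic	assigned
35	PCG	Posterior cingulate gyrus	L	paralimbic	assigned
36	PCG	Posterior cingulate gyrus	R	paralimbic	assigned
37	HIP	Hippocampus	L	paralimbic	mirrored
38	HIP	Hippocampus	R	paralimbic	reported
39	PHG	Parahippocampal gyrus	L	paralimbic	reported
40	PHG	Parahippocampal gyrus	R	paralimbic	reported
41	AMYG	Amygdala	L	paralimbic	assigned
42	AMYG	Amygdala	R	paralimbic	assigned
43	CAL	Calcarine fissure and surrounding cortex	L	primary	assigned
44	CAL	Calcarine fissure and surrounding cortex	R	primary	assigned
45	CUN	Cuneus	L	association	mirrored
46	CUN	Cuneus	R	association	reported
47	LING	Lingual gyrus	L	association	assigned
48	LING	Lingual gyrus	R	association	assigned
49	SOG	Superior occipital gyrus	L	association	reported
50	SOG	Superior occipital gyrus	R	association	mirrored
51	MOG	Middle occipital gyrus	L	association	reported
52	MOG	Middle occipital gyrus	R	association	mirrored
53	IOG	Inferior occipital gyrus	L	association	assigned
54	IOG	Inferior occipital gyrus	R	association	assigned
55	FFG	Fusiform gyrus	L	association	mirrored
56	FFG	Fusiform gyrus	R	association	reported
57	PoCG	Postcentral gyrus	L	paralimbic	reported
58	PoCG	Postcentral gyrus	R	paralimbic	mirrored
59	SPG	Superior parietal gyrus	L	association	reported
60	SPG	Superior parietal gyrus	R	association	reported
61	IPL	Inferior parietal, but supramarginal and angular gyri	L	association	assigned
62	IPL	Inferior parietal, but supramarginal and angular gyri	R	association	assigned
63	SMG	Supramarginal gyrus	L	association	reported
64	SMG	Supramarginal gyrus	R	association	mirrored
65	ANG	Angular gyrus	L	association	reported
66	ANG	Angular gyrus	R	association	reported
67	PCUN	Precuneus	L	association	reported
68	PCUN	Precuneus	R	association	reported
69	PCL	Paracentral lobule	L	association	mirrored
70	PCL	Paracentral lobule	R	association	reported
71	CAU	Caudate nucleus	L	subcortical	mirrored
72	CAU	Caudate nucleus	R	subcortical	reported
73	PUT	Lenticular nucleus, putamen	L	subcortical	assigned
74	PUT	Lenticular nucleus, putamen	R	subcortical	assigned
75	PAL	Lenticular nucleus, pallidum	L	subcortical	assigned
76	PAL	Lenticular nucleus, pallidum	R	subcortical	assigned
77	THA	Thalamus	L	subcortical	mirrored
78	THA	Thalamus	R	subcortical	reported
79	HES	Heschl gyrus	L	paralimbic	reported
80	HES	Heschl gyrus	R	paralimbic	reported
81	STG	Superior temporal gyrus	L	association	mirrored
82	STG	Superior temporal gyrus	R	association	reported
83	TPOsup	Temporal pole: superior temporal gyrus	L	paralimbic	reported
84	TPOsup	Temporal pole: superior temporal gyrus	R	paralimbic	mirrored
85	MTG	Middle temporal gyrus	L	association	assigned
86	MTG	Middle temporal gyrus	R	association	assigned
87	TPOmid	Temporal pole: middle temporal gyrus	L	paralimbic	assigned
88	TPOmid	Temporal pole: middle temporal gyrus	R	paralimbic	assigned
89	ITG	Inferior temporal gyrus	L	association	assigned
90	ITG	Inferior temporal gyrus	R	association	assigned
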
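index	roi_id	name	hemisphere	pair_id
1	MCP	Middle cerebellar peduncle	M	MCP
2	PCT	Pontine crossing tract	M	PCT
3	GCC	Genu of corpus callosum	M	GCC
4	BCC	Body of corpus callosum	M	BCC
5	SCC	Splenium of corpus callosum	M	SCC
6	FX	Fornix (column and body)	M	FX
7	CST-R	Corticospinal tract	R	CST
8	CST-L	Corticospinal tract	L	CST
9	ML-R	Medial lemniscus	R	ML
10	ML-L	Medial lemniscus	L	ML
11	ICP-R	Inferior cerebellar peduncle	R	ICP
12	ICP-L	Inferior cerebellar peduncle	L	ICP
13	SCP-R	Superior cerebellar peduncle	R	SCP
14	SCP-L	Superior cerebellar peduncle	L	SCP
15	CP-R	Cerebral peduncle	R	CP
16	CP-L	Cerebral peduncle	L	CP
17	ALIC-R	Anterior limb of internal capsule	R	ALIC
18	ALIC-L	Anterior limb of internal capsule	L	ALIC
19	PLIC-R	Posterior limb of internal capsule	R	PLIC
20	PLIC-L	Posterior limb of internal capsule	L	PLIC
21	RLIC-R	Retrolenticular part of internal capsule	R	RLIC
22	RLIC-L	Retrolenticular part of internal capsule	L	RLIC
23	ACR-R	Anterior corona radiata	R	ACR
24	ACR-L	Anterior corona radiata	L	ACR
25	SCR-R	Superior corona radiata	R	SCR
26	SCR-L	Superior corona radiata	L	SCR
27	PCR-R	Posterior corona radiata	R	PCR
28	PCR-L	Posterior corona radiata	L	PCR
29	PTR-R	Posterior thalamic radiation	R	PTR
30	PTR-L	Posterior thalamic radiation	L	PTR
31	SS-R	Sagittal stratum	R	SS
32	SS-L	Sagittal stratum	L	SS
33	EC-R	External capsule	R	EC
34	EC-L	External capsule	L	EC
35	CGC-R	Cingulum (cingulate gyrus)	R	CGC
36	CGC-L	Cingulum (cingulate gyrus)	L	CGC
37	CGH-R	Cingulum (hippocampus)	R	CGH
38	CGH-L	Cingulum (hippocampus)	L	CGH
39	FXST-R	Fornix (cres) / Stria terminalis	R	FXST
40	FXST-L	Fornix (cres) / Stria terminalis	L	FXST
41	SLF-R	Superior longitudinal fasciculus	R	SLF
42	SLF-L	Superior longitudinal fasciculus	L	SLF
43	SFO-R	Superior fronto-occipital fasciculus	R	SFO
44	SFO-L	Superior fronto-occipital fasciculus	L	SFO
45	UNC-R	Uncinate fasciculus	R	UNC
46	UNC-L	Uncinate fasciculus	L	UNC
47	TAP-R	Tapetum	R	TAP
48	TAP-L	Tapetum	L	TAP
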
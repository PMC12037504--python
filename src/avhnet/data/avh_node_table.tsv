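index	label	abbrev	x	y	z
1	Right Temporal pole	Tpole.R	58	3	-24
2	Right Fusiform gyrus/BA19	BA19.R	20	-64	-24
3	Left BA19	BA19.L	-25	-58	-23
4	Left parahippocampus	PHP.L	-35	-26	-22
5	Right orbital frontal cortex	OFC.R	27	36	-21
6	Left Inferior frontal gyrus	IFG.L	-45	19	-21
7	Inferior medial prefrontal cortex	MPFC	2	39	-19
8	Right inferior putaman	IPUT.R	24	7	-19
9	Left BA21	BA21	-62	-26	-18
10	Left primary visual cortex	VIS.L	-17	-66	-17
11	Left putamen	PUT.L	-18	15	-16
12	Right superior putamen	DPUT.R	23	11	-10
13	Right insula/auditory cortex	INS.L	41	-8	-10
14	Right lateral prefrontal cortex	LPFC.R	55	25	5
15	Medial prefrontal cortex	MFC	-8	61	6
16	Left lateral prefrontal cortex	LPFC.L	-52	24	8
17	Left BA19	BA19.L	-30	-85	9
18	Right BA40	BA40.R	60	-39	18
19	Right lateral prefrontal cortex	PFC.R	53	13	19
20	Posterior cingulated cortex	PCC	3	-39	20
21	Left sensory cortex	SEN.L	-59	-21	21
22	Left superior prefrontal cortex	SPFC.L	-51	17	28
23	Anterior cingulate	ACC	11	16	30
24	Left BA39	BA39.L	-53	-45	30
25	Right sensory cortex	SEN.R	42	-29	34
26	Left Temporoparietal Junction	TPJ.L	-50	-40	20
27	Left Superior Temporal Gyrus	STG.L	-60	-30	10
28	Right Middle Temporal Gyrus	MTG.R	50	-50	10
29	Left Inferior Temporal Gyrus	ITG.L	-55	-60	-5
30	Right Superior Frontal Gyrus	SFG.R	20	60	20
31	Left Inferior Parietal Lobule	IPL.L	-45	-50	40
32	Supplementary Motor Area	SMA	10	0	60
33	Posterior Cingulate Cortex	PCC	3	-39	20
34	Right Putamen	PUT.L	24	7	-19
35	Primary Visual Cortex	VIS.R	17	-66	-17
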
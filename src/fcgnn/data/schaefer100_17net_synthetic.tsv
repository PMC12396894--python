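region_index	region_name	hemisphere	network17	network_group
0	LH_VisCent_Striate_1	LH	VisCent	VN
1	LH_SalVentAttnA_Ins_1	LH	SalVentAttnA	VAN
2	LH_DefaultC_Rsp_1	LH	DefaultC	DMN
3	LH_LimbicA_TempPole_1	LH	LimbicA	LMB
4	LH_DefaultB_PFCv_1	LH	DefaultB	DMN
5	LH_DefaultB_Temp_2	LH	DefaultB	DMN
6	LH_VisPeri_StriCal_1	LH	VisPeri	VN
7	LH_ContC_pCun_1	LH	ContC	CN
8	LH_SomMotA_2	LH	SomMotA	SM
9	LH_DorsAttnB_PostC_2	LH	DorsAttnB	DAN
10	LH_SomMotB_Cent_1	LH	SomMotB	SM
11	LH_SomMotA_1	LH	SomMotA	SM
12	LH_SalVentAttnA_Ins_2	LH	SalVentAttnA	VAN
13	LH_SomMotB_S2_2	LH	SomMotB	SM
14	LH_SalVentAttnA_FrMed_1	LH	SalVentAttnA	VAN
15	LH_ContA_IPS_1	LH	ContA	CN
16	LH_DefaultA_PFCm_1	LH	DefaultA	DMN
17	LH_DorsAttnB_PostC_1	LH	DorsAttnB	DAN
18	LH_DefaultB_Temp_1	LH	DefaultB	DMN
19	LH_SomMotB_S2_1	LH	SomMotB	SM
20	LH_DefaultB_PFCd_1	LH	DefaultB	DMN
21	LH_ContA_PFCl_2	LH	ContA	CN
22	LH_VisCent_ExStr_1	LH	VisCent	VN
23	LH_VisCent_ExStr_2	LH	VisCent	VN
24	LH_VisCent_Striate_2	LH	VisCent	VN
25	LH_VisCent_ExStr_3	LH	VisCent	VN
26	LH_VisPeri_ExStrSup_1	LH	VisPeri	VN
27	LH_SomMotA_3	LH	SomMotA	SM
28	LH_SomMotA_4	LH	SomMotA	SM
29	LH_SomMotA_5	LH	SomMotA	SM
30	LH_SomMotB_Aud_1	LH	SomMotB	SM
31	LH_DorsAttnA_SPL_1	LH	DorsAttnA	DAN
32	LH_DorsAttnA_TempOcc_1	LH	DorsAttnA	DAN
33	LH_DorsAttnB_FEF_1	LH	DorsAttnB	DAN
34	LH_DorsAttnB_PostC_3	LH	DorsAttnB	DAN
35	LH_SalVentAttnA_ParMed_1	LH	SalVentAttnA	VAN
36	LH_SalVentAttnB_PFCmp_1	LH	SalVentAttnB	VAN
37	LH_SalVentAttnB_IPL_1	LH	SalVentAttnB	VAN
38	LH_LimbicA_TempPole_2	LH	LimbicA	LMB
39	LH_LimbicB_OFC_1	LH	LimbicB	LMB
40	LH_ContA_PFCd_1	LH	ContA	CN
41	LH_ContA_Cingm_1	LH	ContA	CN
42	LH_ContB_Temp_1	LH	ContB	CN
43	LH_ContC_Cingp_1	LH	ContC	CN
44	LH_DefaultA_PFCd_1	LH	DefaultA	DMN
45	LH_DefaultA_IPL_1	LH	DefaultA	DMN
46	LH_DefaultB_PFCl_1	LH	DefaultB	DMN
47	LH_DefaultC_PHC_1	LH	DefaultC	DMN
48	LH_DefaultC_IPL_1	LH	DefaultC	DMN
49	LH_TempPar_1	LH	TempPar	TPN
50	LH_TempPar_3	LH	TempPar	TPN
51	RH_VisPeri_StriCal_1	RH	VisPeri	VN
52	RH_DefaultB_PFCv_1	RH	DefaultB	DMN
53	RH_DefaultC_Rsp_1	RH	DefaultC	DMN
54	RH_LimbicA_TempPole_1	RH	LimbicA	LMB
55	RH_SalVentAttnA_Ins_1	RH	SalVentAttnA	VAN
56	RH_VisPeri_ExStrInf_1	RH	VisPeri	VN
57	RH_TempPar_2	RH	TempPar	TPN
58	RH_SalVentAttnB_PFCl_1	RH	SalVentAttnB	VAN
59	RH_ContB_PFClv_1	RH	ContB	CN
60	RH_SomMotB_S2_2	RH	SomMotB	SM
61	RH_ContC_pCun_1	RH	ContC	CN
62	RH_SomMotB_Cent_1	RH	SomMotB	SM
63	RH_DefaultA_pCunPCC_1	RH	DefaultA	DMN
64	RH_SalVentAttnA_FrMed_1	RH	SalVentAttnA	VAN
65	RH_DefaultA_PFCm_1	RH	DefaultA	DMN
66	RH_SalVentAttnA_ParOper_1	RH	SalVentAttnA	VAN
67	RH_DefaultB_PFCd_1	RH	DefaultB	DMN
68	RH_ContB_IPL_1	RH	ContB	CN
69	RH_DorsAttnA_ParOcc_1	RH	DorsAttnA	DAN
70	RH_ContB_PFCld_1	RH	ContB	CN
71	RH_ContA_PFCl_2	RH	ContA	CN
72	RH_VisCent_ExStr_1	RH	VisCent	VN
73	RH_VisCent_ExStr_2	RH	VisCent	VN
74	RH_VisCent_Striate_2	RH	VisCent	VN
75	RH_VisCent_ExStr_3	RH	VisCent	VN
76	RH_VisPeri_ExStrSup_1	RH	VisPeri	VN
77	RH_SomMotA_3	RH	SomMotA	SM
78	RH_SomMotA_4	RH	SomMotA	SM
79	RH_SomMotA_5	RH	SomMotA	SM
80	RH_SomMotB_Aud_1	RH	SomMotB	SM
81	RH_DorsAttnA_SPL_1	RH	DorsAttnA	DAN
82	RH_DorsAttnA_TempOcc_1	RH	DorsAttnA	DAN
83	RH_DorsAttnB_FEF_1	RH	DorsAttnB	DAN
84	RH_DorsAttnB_PostC_3	RH	DorsAttnB	DAN
85	RH_SalVentAttnA_ParMed_1	RH	SalVentAttnA	VAN
86	RH_SalVentAttnB_PFCmp_1	RH	SalVentAttnB	VAN
87	RH_SalVentAttnB_IPL_1	RH	SalVentAttnB	VAN
88	RH_LimbicA_TempPole_2	RH	LimbicA	LMB
89	RH_LimbicB_OFC_1	RH	LimbicB	LMB
90	RH_ContA_PFCd_1	RH	ContA	CN
91	RH_ContA_Cingm_1	RH	ContA	CN
92	RH_ContB_Temp_1	RH	ContB	CN
93	RH_ContC_Cingp_1	RH	ContC	CN
94	RH_DefaultA_PFCd_1	RH	DefaultA	DMN
95	RH_DefaultA_IPL_1	RH	DefaultA	DMN
96	RH_DefaultB_PFCl_1	RH	DefaultB	DMN
97	RH_DefaultC_PHC_1	RH	DefaultC	DMN
98	RH_DefaultC_IPL_1	RH	DefaultC	DMN
99	RH_TempPar_1	RH	TempPar	TPN
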
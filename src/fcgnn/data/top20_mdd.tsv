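rank	region_i	region_j
1	LH_VisCent_Striate_1	RH_VisPeri_StriCal_1
2	LH_SalVentAttnA_Ins_1	RH_DefaultB_PFCv_1
3	LH_DefaultC_Rsp_1	RH_DefaultC_Rsp_1
4	LH_LimbicA_TempPole_1	RH_LimbicA_TempPole_1
5	RH_SalVentAttnA_Ins_1	RH_DefaultB_PFCv_1
6	LH_DefaultC_Rsp_1	RH_VisPeri_ExStrInf_1
7	LH_DefaultB_PFCv_1	RH_DefaultB_PFCv_1
8	RH_VisPeri_StriCal_1	RH_LimbicA_TempPole_1
9	LH_DefaultB_Temp_2	RH_TempPar_2
10	RH_SalVentAttnB_PFCl_1	RH_ContB_PFClv_1
11	LH_VisCent_Striate_1	RH_SalVentAttnB_PFCl_1
12	LH_VisPeri_StriCal_1	LH_DefaultC_Rsp_1
13	LH_SalVentAttnA_Ins_1	LH_DefaultB_Temp_2
14	RH_SomMotB_S2_2	RH_DefaultB_PFCv_1
15	LH_ContC_pCun_1	RH_ContC_pCun_1
16	LH_SomMotA_2	LH_DorsAttnB_PostC_2
17	LH_SomMotB_Cent_1	RH_SomMotB_Cent_1
18	LH_SomMotA_1	RH_DefaultA_pCunPCC_1
19	LH_SomMotA_2	LH_SomMotB_Cent_1
20	LH_VisPeri_StriCal_1	RH_VisPeri_ExStrInf_1
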
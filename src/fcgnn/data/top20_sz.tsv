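rank	region_i	region_j
1	LH_SalVentAttnA_Ins_2	RH_SalVentAttnA_Ins_1
2	LH_SalVentAttnA_Ins_2	RH_SalVentAttnA_FrMed_1
3	LH_VisCent_Striate_1	RH_VisPeri_StriCal_1
4	LH_SomMotB_S2_2	LH_SalVentAttnA_Ins_2
5	LH_SalVentAttnA_Ins_1	LH_SalVentAttnA_Ins_2
6	LH_SalVentAttnA_Ins_1	RH_SalVentAttnA_Ins_1
7	LH_SalVentAttnA_Ins_2	LH_SalVentAttnA_FrMed_1
8	LH_SalVentAttnA_Ins_2	LH_ContA_IPS_1
9	LH_DefaultA_PFCm_1	RH_DefaultA_PFCm_1
10	LH_DorsAttnB_PostC_1	LH_SalVentAttnA_Ins_2
11	RH_SomMotB_Cent_1	RH_SalVentAttnA_ParOper_1
12	LH_SalVentAttnA_Ins_2	LH_DefaultB_PFCv_1
13	LH_SalVentAttnA_Ins_1	LH_DefaultB_Temp_1
14	LH_SomMotB_S2_1	LH_SalVentAttnA_Ins_2
15	LH_DefaultB_Temp_1	LH_DefaultB_PFCd_1
16	RH_DefaultA_PFCm_1	RH_DefaultB_PFCd_1
17	LH_DefaultB_Temp_1	RH_ContB_IPL_1
18	RH_DorsAttnA_ParOcc_1	RH_ContB_PFCld_1
19	RH_ContA_PFCl_2	RH_ContB_PFCld_1
20	LH_SalVentAttnA_Ins_2	LH_ContA_PFCl_2
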
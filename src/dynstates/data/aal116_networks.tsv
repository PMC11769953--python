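region_label	network
Precentral_L	SMN
Precentral_R	SMN
Frontal_Sup_L	FPN
Frontal_Sup_R	FPN
Frontal_Sup_Orb_L	ND
Frontal_Sup_Orb_R	ND
Frontal_Mid_L	FPN
Frontal_Mid_R	FPN
Frontal_Mid_Orb_L	ND
Frontal_Mid_Orb_R	ND
Frontal_Inf_Oper_L	CON
Frontal_Inf_Oper_R	CON
Frontal_Inf_Tri_L	FPN
Frontal_Inf_Tri_R	FPN
Frontal_Inf_Orb_L	ND
Frontal_Inf_Orb_R	ND
Rolandic_Oper_L	AUD
Rolandic_Oper_R	AUD
Supp_Motor_Area_L	SMN
Supp_Motor_Area_R	SMN
Olfactory_L	SUB
Olfactory_R	SUB
Frontal_Sup_Medial_L	DMN
Frontal_Sup_Medial_R	DMN
Frontal_Med_Orb_L	DMN
Frontal_Med_Orb_R	DMN
Rectus_L	ND
Rectus_R	ND
Insula_L	CON
Insula_R	CON
Cingulum_Ant_L	CON
Cingulum_Ant_R	CON
Cingulum_Mid_L	CON
Cingulum_Mid_R	CON
Cingulum_Post_L	DMN
Cingulum_Post_R	DMN
Hippocampus_L	SUB
Hippocampus_R	SUB
ParaHippocampal_L	SUB
ParaHippocampal_R	SUB
Amygdala_L	SUB
Amygdala_R	SUB
Calcarine_L	VIS
Calcarine_R	VIS
Cuneus_L	VIS
Cuneus_R	VIS
Lingual_L	VIS
Lingual_R	VIS
Occipital_Sup_L	VIS
Occipital_Sup_R	VIS
Occipital_Mid_L	VIS
Occipital_Mid_R	VIS
Occipital_Inf_L	VIS
Occipital_Inf_R	VIS
Fusiform_L	VIS
Fusiform_R	VIS
Postcentral_L	SMN
Postcentral_R	SMN
Parietal_Sup_L	FPN
Parietal_Sup_R	FPN
Parietal_Inf_L	FPN
Parietal_Inf_R	FPN
SupraMarginal_L	ATT
SupraMarginal_R	ATT
Angular_L	DMN
Angular_R	DMN
Precuneus_L	DMN
Precuneus_R	DMN
Paracentral_Lobule_L	SMN
Paracentral_Lobule_R	SMN
Caudate_L	SUB
Caudate_R	SUB
Putamen_L	SUB
Putamen_R	SUB
Pallidum_L	SUB
Pallidum_R	SUB
Thalamus_L	SUB
Thalamus_R	SUB
Heschl_L	AUD
Heschl_R	AUD
Temporal_Sup_L	AUD
Temporal_Sup_R	AUD
Temporal_Pole_Sup_L	ND
Temporal_Pole_Sup_R	ND
Temporal_Mid_L	DMN
Temporal_Mid_R	DMN
Temporal_Pole_Mid_L	ND
Temporal_Pole_Mid_R	ND
Temporal_Inf_L	ND
Temporal_Inf_R	ND
Cerebelum_Crus1_L	CN
Cerebelum_Crus1_R	CN
Cerebelum_Crus2_L	CN
Cerebelum_Crus2_R	CN
Cerebelum_3_L	CN
Cerebelum_3_R	CN
Cerebelum_4_5_L	CN
Cerebelum_4_5_R	CN
Cerebelum_6_L	CN
Cerebelum_6_R	CN
Cerebelum_7b_L	CN
Cerebelum_7b_R	CN
Cerebelum_8_L	CN
Cerebelum_8_R	CN
Cerebelum_9_L	CN
Cerebelum_9_R	CN
Cerebelum_10_L	CN
Cerebelum_10_R	CN
Vermis_1_2	CN
Vermis_3	CN
Vermis_4_5	CN
Vermis_6	CN
Vermis_7	CN
Vermis_8	CN
Vermis_9	CN
Vermis_10	CN
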
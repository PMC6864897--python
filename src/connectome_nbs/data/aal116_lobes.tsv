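node_label	division
Precentral_L	frontal
Precentral_R	frontal
Frontal_Sup_L	frontal
Frontal_Sup_R	frontal
Frontal_Sup_Orb_L	frontal
Frontal_Sup_Orb_R	frontal
Frontal_Mid_L	frontal
Frontal_Mid_R	frontal
Frontal_Mid_Orb_L	frontal
Frontal_Mid_Orb_R	frontal
Frontal_Inf_Oper_L	frontal
Frontal_Inf_Oper_R	frontal
Frontal_Inf_Tri_L	frontal
Frontal_Inf_Tri_R	frontal
Frontal_Inf_Orb_L	frontal
Frontal_Inf_Orb_R	frontal
Rolandic_Oper_L	frontal
Rolandic_Oper_R	frontal
Supp_Motor_Area_L	frontal
Supp_Motor_Area_R	frontal
Olfactory_L	frontal
Olfactory_R	frontal
Frontal_Sup_Medial_L	frontal
Frontal_Sup_Medial_R	frontal
Frontal_Med_Orb_L	frontal
Frontal_Med_Orb_R	frontal
Rectus_L	frontal
Rectus_R	frontal
Insula_L	subcortical
Insula_R	subcortical
Cingulum_Ant_L	cingulate
Cingulum_Ant_R	cingulate
Cingulum_Mid_L	cingulate
Cingulum_Mid_R	cingulate
Cingulum_Post_L	cingulate
Cingulum_Post_R	cingulate
Hippocampus_L	subcortical
Hippocampus_R	subcortical
ParaHippocampal_L	subcortical
ParaHippocampal_R	subcortical
Amygdala_L	subcortical
Amygdala_R	subcortical
Calcarine_L	occipital
Calcarine_R	occipital
Cuneus_L	occipital
Cuneus_R	occipital
Lingual_L	occipital
Lingual_R	occipital
Occipital_Sup_L	occipital
Occipital_Sup_R	occipital
Occipital_Mid_L	occipital
Occipital_Mid_R	occipital
Occipital_Inf_L	occipital
Occipital_Inf_R	occipital
Fusiform_L	temporal
Fusiform_R	temporal
Postcentral_L	parietal
Postcentral_R	parietal
Parietal_Sup_L	parietal
Parietal_Sup_R	parietal
Parietal_Inf_L	parietal
Parietal_Inf_R	parietal
SupraMarginal_L	parietal
SupraMarginal_R	parietal
Angular_L	parietal
Angular_R	parietal
Precuneus_L	parietal
Precuneus_R	parietal
Paracentral_Lobule_L	frontal
Paracentral_Lobule_R	frontal
Caudate_L	subcortical
Caudate_R	subcortical
Putamen_L	subcortical
Putamen_R	subcortical
Pallidum_L	subcortical
Pallidum_R	subcortical
Thalamus_L	subcortical
Thalamus_R	subcortical
Heschl_L	temporal
Heschl_R	temporal
Temporal_Sup_L	temporal
Temporal_Sup_R	temporal
Temporal_Pole_Sup_L	temporal
Temporal_Pole_Sup_R	temporal
Temporal_Mid_L	temporal
Temporal_Mid_R	temporal
Temporal_Pole_Mid_L	temporal
Temporal_Pole_Mid_R	temporal
Temporal_Inf_L	temporal
Temporal_Inf_R	temporal
Cerebelum_Crus1_L	subcortical
Cerebelum_Crus1_R	subcortical
Cerebelum_Crus2_L	subcortical
Cerebelum_Crus2_R	subcortical
Cerebelum_3_L	subcortical
Cerebelum_3_R	subcortical
Cerebelum_4_5_L	subcortical
Cerebelum_4_5_R	subcortical
Cerebelum_6_L	subcortical
Cerebelum_6_R	subcortical
Cerebelum_7b_L	subcortical
Cerebelum_7b_R	subcortical
Cerebelum_8_L	subcortical
Cerebelum_8_R	subcortical
Cerebelum_9_L	subcortical
Cerebelum_9_R	subcortical
Cerebelum_10_L	subcortical
Cerebelum_10_R	subcortical
Vermis_1_2	subcortical
Vermis_3	subcortical
Vermis_4_5	subcortical
Vermis_6	subcortical
Vermis_7	subcortical
Vermis_8	subcortical
Vermis_9	subcortical
Vermis_10	subcortical
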
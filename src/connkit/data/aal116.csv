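region_id,name,hemisphere,lobe,category,canonical_network
0,Precentral_L,L,frontal,cortical,sensorimotor
1,Precentral_R,R,frontal,cortical,sensorimotor
2,Frontal_Sup_L,L,frontal,cortical,frontoparietal
3,Frontal_Sup_R,R,frontal,cortical,frontoparietal
4,Frontal_Sup_Orb_L,L,frontal,cortical,default_mode
5,Frontal_Sup_Orb_R,R,frontal,cortical,default_mode
6,Frontal_Mid_L,L,frontal,cortical,frontoparietal
7,Frontal_Mid_R,R,frontal,cortical,frontoparietal
8,Frontal_Mid_Orb_L,L,frontal,cortical,default_mode
9,Frontal_Mid_Orb_R,R,frontal,cortical,default_mode
10,Frontal_Inf_Oper_L,L,frontal,cortical,frontoparietal
11,Frontal_Inf_Oper_R,R,frontal,cortical,frontoparietal
12,Frontal_Inf_Tri_L,L,frontal,cortical,frontoparietal
13,Frontal_Inf_Tri_R,R,frontal,cortical,frontoparietal
14,Frontal_Inf_Orb_L,L,frontal,cortical,default_mode
15,Frontal_Inf_Orb_R,R,frontal,cortical,default_mode
16,Rolandic_Oper_L,L,frontal,cortical,sensorimotor
17,Rolandic_Oper_R,R,frontal,cortical,sensorimotor
18,Supp_Motor_Area_L,L,frontal,cortical,sensorimotor
19,Supp_Motor_Area_R,R,frontal,cortical,sensorimotor
20,Olfactory_L,L,frontal,cortical,default_mode
21,Olfactory_R,R,frontal,cortical,default_mode
22,Frontal_Sup_Medial_L,L,frontal,cortical,default_mode
23,Frontal_Sup_Medial_R,R,frontal,cortical,default_mode
24,Frontal_Med_Orb_L,L,frontal,cortical,default_mode
25,Frontal_Med_Orb_R,R,frontal,cortical,default_mode
26,Rectus_L,L,frontal,cortical,default_mode
27,Rectus_R,R,frontal,cortical,default_mode
28,Insula_L,L,insula,cortical,salience
29,Insula_R,R,insula,cortical,salience
30,Cingulum_Ant_L,L,limbic,cortical,default_mode
31,Cingulum_Ant_R,R,limbic,cortical,default_mode
32,Cingulum_Mid_L,L,limbic,cortical,salience
33,Cingulum_Mid_R,R,limbic,cortical,salience
34,Cingulum_Post_L,L,limbic,cortical,default_mode
35,Cingulum_Post_R,R,limbic,cortical,default_mode
36,Hippocampus_L,L,subcortical,subcortical,subcortical
37,Hippocampus_R,R,subcortical,subcortical,subcortical
38,ParaHippocampal_L,L,limbic,cortical,default_mode
39,ParaHippocampal_R,R,limbic,cortical,default_mode
40,Amygdala_L,L,subcortical,subcortical,subcortical
41,Amygdala_R,R,subcortical,subcortical,subcortical
42,Calcarine_L,L,occipital,cortical,visual
43,Calcarine_R,R,occipital,cortical,visual
44,Cuneus_L,L,occipital,cortical,visual
45,Cuneus_R,R,occipital,cortical,visual
46,Lingual_L,L,occipital,cortical,visual
47,Lingual_R,R,occipital,cortical,visual
48,Occipital_Sup_L,L,occipital,cortical,visual
49,Occipital_Sup_R,R,occipital,cortical,visual
50,Occipital_Mid_L,L,occipital,cortical,visual
51,Occipital_Mid_R,R,occipital,cortical,visual
52,Occipital_Inf_L,L,occipital,cortical,visual
53,Occipital_Inf_R,R,occipital,cortical,visual
54,Fusiform_L,L,occipital,cortical,visual
55,Fusiform_R,R,occipital,cortical,visual
56,Postcentral_L,L,parietal,cortical,sensorimotor
57,Postcentral_R,R,parietal,cortical,sensorimotor
58,Parietal_Sup_L,L,parietal,cortical,frontoparietal
59,Parietal_Sup_R,R,parietal,cortical,frontoparietal
60,Parietal_Inf_L,L,parietal,cortical,frontoparietal
61,Parietal_Inf_R,R,parietal,cortical,frontoparietal
62,SupraMarginal_L,L,parietal,cortical,frontoparietal
63,SupraMarginal_R,R,parietal,cortical,frontoparietal
64,Angular_L,L,parietal,cortical,default_mode
65,Angular_R,R,parietal,cortical,default_mode
66,Precuneus_L,L,parietal,cortical,default_mode
67,Precuneus_R,R,parietal,cortical,default_mode
68,Paracentral_Lobule_L,L,frontal,cortical,sensorimotor
69,Paracentral_Lobule_R,R,frontal,cortical,sensorimotor
70,Caudate_L,L,subcortical,subcortical,subcortical
71,Caudate_R,R,subcortical,subcortical,subcortical
72,Putamen_L,L,subcortical,subcortical,subcortical
73,Putamen_R,R,subcortical,subcortical,subcortical
74,Pallidum_L,L,subcortical,subcortical,subcortical
75,Pallidum_R,R,subcortical,subcortical,subcortical
76,Thalamus_L,L,subcortical,subcortical,subcortical
77,Thalamus_R,R,subcortical,subcortical,subcortical
78,Heschl_L,L,temporal,cortical,auditory
79,Heschl_R,R,temporal,cortical,auditory
80,Temporal_Sup_L,L,temporal,cortical,auditory
81,Temporal_Sup_R,R,temporal,cortical,auditory
82,Temporal_Pole_Sup_L,L,temporal,cortical,default_mode
83,Temporal_Pole_Sup_R,R,temporal,cortical,default_mode
84,Temporal_Mid_L,L,temporal,cortical,default_mode
85,Temporal_Mid_R,R,temporal,cortical,default_mode
86,Temporal_Pole_Mid_L,L,temporal,cortical,default_mode
87,Temporal_Pole_Mid_R,R,temporal,cortical,default_mode
88,Temporal_Inf_L,L,temporal,cortical,visual
89,Temporal_Inf_R,R,temporal,cortical,visual
90,Cerebelum_Crus1_L,L,cerebellum,cerebellar,cerebellum
91,Cerebelum_Crus1_R,R,cerebellum,cerebellar,cerebellum
92,Cerebelum_Crus2_L,L,cerebellum,cerebellar,cerebellum
93,Cerebelum_Crus2_R,R,cerebellum,cerebellar,cerebellum
94,Cerebelum_3_L,L,cerebellum,cerebellar,cerebellum
95,Cerebelum_3_R,R,cerebellum,cerebellar,cerebellum
96,Cerebelum_4_5_L,L,cerebellum,cerebellar,cerebellum
97,Cerebelum_4_5_R,R,cerebellum,cerebellar,cerebellum
98,Cerebelum_6_L,L,cerebellum,cerebellar,cerebellum
99,Cerebelum_6_R,R,cerebellum,cerebellar,cerebellum
100,Cerebelum_7b_L,L,cerebellum,cerebellar,cerebellum
101,Cerebelum_7b_R,R,cerebellum,cerebellar,cerebellum
102,Cerebelum_8_L,L,cerebellum,cerebellar,cerebellum
103,Cerebelum_8_R,R,cerebellum,cerebellar,cerebellum
104,Cerebelum_9_L,L,cerebellum,cerebellar,cerebellum
105,Cerebelum_9_R,R,cerebellum,cerebellar,cerebellum
106,Cerebelum_10_L,L,cerebellum,cerebellar,cerebellum
107,Cerebelum_10_R,R,cerebellum,cerebellar,cerebellum
108,Vermis_1_2,M,cerebellum,cerebellar,cerebellum
109,Vermis_3,M,cerebellum,cerebellar,cerebellum
110,Vermis_4_5,M,cerebellum,cerebellar,cerebellum
111,Vermis_6,M,cerebellum,cerebellar,cerebellum
112,Vermis_7,M,cerebellum,cerebellar,cerebellum
113,Vermis_8,M,cerebellum,cerebellar,cerebellum
114,Vermis_9,M,cerebellum,cerebellar,cerebellum
115,Vermis_10,M,cerebellum,cerebellar,cerebellum
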
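aal_index,name,hemisphere,cortical
1,Precentral_L,L,1
2,Precentral_R,R,1
3,Frontal_Sup_L,L,1
4,Frontal_Sup_R,R,1
5,Frontal_Sup_Orb_L,L,1
6,Frontal_Sup_Orb_R,R,1
7,Frontal_Mid_L,L,1
8,Frontal_Mid_R,R,1
9,Frontal_Mid_Orb_L,L,1
10,Frontal_Mid_Orb_R,R,1
11,Frontal_Inf_Oper_L,L,1
12,Frontal_Inf_Oper_R,R,1
13,Frontal_Inf_Tri_L,L,1
14,Frontal_Inf_Tri_R,R,1
15,Frontal_Inf_Orb_L,L,1
16,Frontal_Inf_Orb_R,R,1
17,Rolandic_Oper_L,L,1
18,Rolandic_Oper_R,R,1
19,Supp_Motor_Area_L,L,1
20,Supp_Motor_Area_R,R,1
21,Olfactory_L,L,1
22,Olfactory_R,R,1
23,Frontal_Sup_Medial_L,L,1
24,Frontal_Sup_Medial_R,R,1
25,Frontal_Med_Orb_L,L,1
26,Frontal_Med_Orb_R,R,1
27,Rectus_L,L,1
28,Rectus_R,R,1
29,Insula_L,L,1
30,Insula_R,R,1
31,Cingulum_Ant_L,L,1
32,Cingulum_Ant_R,R,1
33,Cingulum_Mid_L,L,1
34,Cingulum_Mid_R,R,1
35,Cingulum_Post_L,L,1
36,Cingulum_Post_R,R,1
37,Hippocampus_L,L,0
38,Hippocampus_R,R,0
39,ParaHippocampal_L,L,1
40,ParaHippocampal_R,R,1
41,Amygdala_L,L,0
42,Amygdala_R,R,0
43,Calcarine_L,L,1
44,Calcarine_R,R,1
45,Cuneus_L,L,1
46,Cuneus_R,R,1
47,Lingual_L,L,1
48,Lingual_R,R,1
49,Occipital_Sup_L,L,1
50,Occipital_Sup_R,R,1
51,Occipital_Mid_L,L,1
52,Occipital_Mid_R,R,1
53,Occipital_Inf_L,L,1
54,Occipital_Inf_R,R,1
55,Fusiform_L,L,1
56,Fusiform_R,R,1
57,Postcentral_L,L,1
58,Postcentral_R,R,1
59,Parietal_Sup_L,L,1
60,Parietal_Sup_R,R,1
61,Parietal_Inf_L,L,1
62,Parietal_Inf_R,R,1
63,SupraMarginal_L,L,1
64,SupraMarginal_R,R,1
65,Angular_L,L,1
66,Angular_R,R,1
67,Precuneus_L,L,1
68,Precuneus_R,R,1
69,Paracentral_Lobule_L,L,1
70,Paracentral_Lobule_R,R,1
71,Caudate_L,L,0
72,Caudate_R,R,0
73,Putamen_L,L,0
74,Putamen_R,R,0
75,Pallidum_L,L,0
76,Pallidum_R,R,0
77,Thalamus_L,L,0
78,Thalamus_R,R,0
79,Heschl_L,L,1
80,Heschl_R,R,1
81,Temporal_Sup_L,L,1
82,Temporal_Sup_R,R,1
83,Temporal_Pole_Sup_L,L,1
84,Temporal_Pole_Sup_R,R,1
85,Temporal_Mid_L,L,1
86,Temporal_Mid_R,R,1
87,Temporal_Pole_Mid_L,L,1
88,Temporal_Pole_Mid_R,R,1
89,Temporal_Inf_L,L,1
90,Temporal_Inf_R,R,1
91,Cerebelum_Crus1_L,L,0
92,Cerebelum_Crus1_R,R,0
93,Cerebelum_Crus2_L,L,0
94,Cerebelum_Crus2_R,R,0
95,Cerebelum_3_L,L,0
96,Cerebelum_3_R,R,0
97,Cerebelum_4_5_L,L,0
98,Cerebelum_4_5_R,R,0
99,Cerebelum_6_L,L,0
100,Cerebelum_6_R,R,0
101,Cerebelum_7b_L,L,0
102,Cerebelum_7b_R,R,0
103,Cerebelum_8_L,L,0
104,Cerebelum_8_R,R,0
105,Cerebelum_9_L,L,0
106,Cerebelum_9_R,R,0
107,Cerebelum_10_L,L,0
108,Cerebelum_10_R,R,0
109,Vermis_1_2,M,0
110,Vermis_3,M,0
111,Vermis_4_5,M,0
112,Vermis_6,M,0
113,Vermis_7,M,0
114,Vermis_8,M,0
115,Vermis_9,M,0
116,Vermis_10,M,0
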
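roi_id,roi,lobe
1,left_superior_frontal,frontal
2,right_superior_frontal,frontal
3,left_superior_frontal_medial,frontal
4,right_superior_frontal_medial,frontal
5,left_middle_frontal,frontal
6,right_middle_frontal,frontal
7,left_middle_frontal_orbital,frontal
8,right_middle_frontal_orbital,frontal
9,left_inferior_frontal_opercular,frontal
10,right_inferior_frontal_opercular,frontal
11,left_inferior_frontal_triangular,frontal
12,right_inferior_frontal_triangular,frontal
13,left_orbitofrontal_medial,frontal
14,right_orbitofrontal_medial,frontal
15,left_orbitofrontal_lateral,frontal
16,right_orbitofrontal_lateral,frontal
17,left_gyrus_rectus,frontal
18,right_gyrus_rectus,frontal
19,left_supplementary_motor,frontal
20,right_supplementary_motor,frontal
21,left_anterior_cingulate,frontal
22,right_anterior_cingulate,frontal
23,left_precentral,sensorimotor
24,right_precentral,sensorimotor
25,left_postcentral,sensorimotor
26,right_postcentral,sensorimotor
27,left_paracentral_lobule,sensorimotor
28,right_paracentral_lobule,sensorimotor
29,left_rolandic_operculum,sensorimotor
30,right_rolandic_operculum,sensorimotor
31,left_hippocampus,medial temporal
32,right_hippocampus,medial temporal
33,left_parahippocampal,medial temporal
34,right_parahippocampal,medial temporal
35,left_amygdala,medial temporal
36,right_amygdala,medial temporal
37,left_entorhinal,medial temporal
38,right_entorhinal,medial temporal
39,left_superior_temporal,lateral temporal
40,right_superior_temporal,lateral temporal
41,left_middle_temporal,lateral temporal
42,right_middle_temporal,lateral temporal
43,left_inferior_temporal,lateral temporal
44,right_inferior_temporal,lateral temporal
45,left_fusiform,lateral temporal
46,right_fusiform,lateral temporal
47,left_temporal_pole_superior,lateral temporal
48,right_temporal_pole_superior,lateral temporal
49,left_temporal_pole_middle,lateral temporal
50,right_temporal_pole_middle,lateral temporal
51,left_heschl,lateral temporal
52,right_heschl,lateral temporal
53,left_precuneus,medial parietal
54,right_precuneus,medial parietal
55,left_posterior_cingulate,medial parietal
56,right_posterior_cingulate,medial parietal
57,left_middle_cingulate,medial parietal
58,right_middle_cingulate,medial parietal
59,left_retrosplenial,medial parietal
60,right_retrosplenial,medial parietal
61,left_superior_parietal,lateral parietal
62,right_superior_parietal,lateral parietal
63,left_inferior_parietal,lateral parietal
64,right_inferior_parietal,lateral parietal
65,left_supramarginal,lateral parietal
66,right_supramarginal,lateral parietal
67,left_angular,lateral parietal
68,right_angular,lateral parietal
69,left_parietal_operculum,lateral parietal
70,right_parietal_operculum,lateral parietal
71,left_calcarine,medial occipital
72,right_calcarine,medial occipital
73,left_cuneus,medial occipital
74,right_cuneus,medial occipital
75,left_lingual,medial occipital
76,right_lingual,medial occipital
77,left_occipital_pole,medial occipital
78,right_occipital_pole,medial occipital
79,left_superior_occipital,lateral occipital
80,right_superior_occipital,lateral occipital
81,left_middle_occipital,lateral occipital
82,right_middle_occipital,lateral occipital
83,left_inferior_occipital,lateral occipital
84,right_inferior_occipital,lateral occipital
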
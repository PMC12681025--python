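lesion_id,age_years,sex,localization,size_mm,subclinical_extension
1,55,F,Forehead,21,Yes
2,72,F,Cheek,20,Yes
3,86,M,Nose,10,No
4,81,F,Nose,7,No
5,61,F,Upper lip,5,No
6,47,M,Forehead,10,Yes
7,79,M,Forehead,15,No
8,66,M,Nose,13,No
9,69,F,Cheek,15,Yes
10,74,F,Cheek,15,Yes
11,71,F,Cheek,21,Yes
14,72,F,Nose,20,Yes
15,75,M,Cheek,15,Yes
16,68,M,Eyebrow,17,No
17,83,M,Upper lip,14,No
18,69,F,Temporal,18,No
19,56,F,Nose,8,Yes
20,65,F,Nose,11,Yes
23,82,M,Medial cantus,10,Yes
24,79,F,Cheek,8,No
25,41,F,Eyebrow,12,Yes
26,86,F,Lower lip,10,No
27,76,F,Upper lip,15,Yes
28,38,M,Nose,15,Yes
30,78,F,Eyebrow,10,Yes
31,72,F,Cheek,15,Yes
32,53,F,Temporal,10,No
33,68,M,Cheek,16,Yes
34,82,M,Nose,12,Yes
36,77,F,Upper lip,15,Yes
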
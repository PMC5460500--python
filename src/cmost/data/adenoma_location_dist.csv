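segment,name,weight
1,rectum,0.09
2,rectosigmoid,0.06
3,sigmoid,0.13
4,sigmoid_descending,0.09
5,descending,0.07
6,splenic_flexure,0.05
7,transverse_distal,0.06
8,transverse,0.07
9,transverse_proximal,0.06
10,hepatic_flexure,0.06
11,ascending,0.10
12,ascending_cecal,0.07
13,cecum,0.09
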
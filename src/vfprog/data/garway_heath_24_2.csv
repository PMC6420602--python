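location_id,x,y,is_blind_spot,gh_angle
1,-9,21,0,268
2,-3,21,0,262
3,3,21,0,252
4,9,21,0,245
5,-15,15,0,264
6,-9,15,0,274
7,-3,15,0,281
8,3,15,0,275
9,9,15,0,260
10,15,15,0,246
11,-21,9,0,271
12,-15,9,0,285
13,-9,9,0,291
14,-3,9,0,296
15,3,9,0,298
16,9,9,0,283
17,15,9,0,253
18,21,9,0,229
19,-27,3,0,278
20,-21,3,0,287
21,-15,3,0,291
22,-9,3,0,298
23,-3,3,0,312
24,3,3,0,329
25,9,3,0,318
26,15,3,1,
27,21,3,0,218
28,-27,-3,0,83
29,-21,-3,0,76
30,-15,-3,0,68
31,-9,-3,0,55
32,-3,-3,0,34
33,3,-3,0,11
34,9,-3,0,13
35,15,-3,1,
36,21,-3,0,167
37,-21,-9,0,85
38,-15,-9,0,78
39,-9,-9,0,66
40,-3,-9,0,56
41,3,-9,0,48
42,9,-9,0,60
43,15,-9,0,95
44,21,-9,0,136
45,-15,-15,0,88
46,-9,-15,0,81
47,-3,-15,0,77
48,3,-15,0,80
49,9,-15,0,93
50,15,-15,0,112
51,-9,-21,0,93
52,-3,-21,0,95
53,3,-21,0,100
54,9,-21,0,108
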
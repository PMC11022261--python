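age_years,sex,q_year
0,female,0.003
1,female,0.000214155
2,female,0.000215646
3,female,0.000217293
4,female,0.000219114
5,female,0.000221126
6,female,0.00022335
7,female,0.000225808
8,female,0.000228525
9,female,0.000231527
10,female,0.000234844
11,female,0.000238511
12,female,0.000242563
13,female,0.000247042
14,female,0.000251991
15,female,0.000257461
16,female,0.000263506
17,female,0.000270187
18,female,0.00027757
19,female,0.00028573
20,female,0.000294748
21,female,0.000304715
22,female,0.000315729
23,female,0.000327902
24,female,0.000341355
25,female,0.000356222
26,female,0.000372653
27,female,0.000390811
28,female,0.000410879
29,female,0.000433057
30,female,0.000457566
31,female,0.000484653
32,female,0.000514588
33,female,0.000547669
34,female,0.000584229
35,female,0.000624632
36,female,0.000669283
37,female,0.000718627
38,female,0.000773158
39,female,0.000833421
40,female,0.000900017
41,female,0.000973612
42,female,0.00105494
43,female,0.00114482
44,female,0.00124413
45,female,0.00135388
46,female,0.00147516
47,female,0.00160918
48,female,0.00175727
49,female,0.00192091
50,female,0.00210173
51,female,0.00230153
52,female,0.0025223
53,female,0.00276622
54,female,0.00303573
55,female,0.00333351
56,female,0.00366249
57,female,0.00402595
58,female,0.00442748
59,female,0.00487105
60,female,0.00536104
61,female,0.00590228
62,female,0.0065001
63,female,0.00716038
64,female,0.00788959
65,female,0.00869487
66,female,0.00958408
67,female,0.0105659
68,female,0.0116498
69,female,0.0128463
70,female,0.014167
71,female,0.0156246
72,female,0.0172329
73,female,0.0190073
74,female,0.0209646
75,female,0.0231233
76,female,0.0255034
77,female,0.028127
78,female,0.0310184
79,female,0.0342039
80,female,0.0377123
81,female,0.0415747
82,female,0.0458254
83,female,0.0505012
84,female,0.055642
85,female,0.0612912
86,female,0.0674952
87,female,0.074304
88,female,0.0817711
89,female,0.0899535
90,female,0.0989116
91,female,0.108709
92,female,0.119413
93,female,0.131094
94,female,0.143823
95,female,0.157674
96,female,0.17272
97,female,0.189037
98,female,0.206696
99,female,0.225765
100,female,0.246307
101,female,0.268376
102,female,0.292015
103,female,0.317253
104,female,0.344099
105,female,0.372543
106,female,0.402545
107,female,0.434037
108,female,0.466914
109,female,0.501031
110,female,1
0,male,0.0035
1,male,0.000430347
2,male,0.000433379
3,male,0.000436713
4,male,0.00044038
5,male,0.000444412
6,male,0.000448846
7,male,0.000453722
8,male,0.000459084
9,male,0.00046498
10,male,0.000471463
11,male,0.000478593
12,male,0.000486433
13,male,0.000495054
14,male,0.000504535
15,male,0.00051496
16,male,0.000526424
17,male,0.00053903
18,male,0.000552893
19,male,0.000568137
20,male,0.000584899
21,male,0.000603332
22,male,0.000623602
23,male,0.000645891
24,male,0.000670401
25,male,0.000697353
26,male,0.00072699
27,male,0.000759579
28,male,0.000795416
29,male,0.000834822
30,male,0.000878153
31,male,0.000925801
32,male,0.000978194
33,male,0.00103581
34,male,0.00109916
35,male,0.00116881
36,male,0.00124541
37,male,0.00132963
38,male,0.00142224
39,male,0.00152406
40,male,0.00163602
41,male,0.00175913
42,male,0.00189448
43,male,0.00204331
44,male,0.00220694
45,male,0.00238684
46,male,0.00258464
47,male,0.00280211
48,male,0.00304119
49,male,0.00330403
50,male,0.00359299
51,male,0.00391065
52,male,0.00425985
53,male,0.0046437
54,male,0.00506565
55,male,0.00552943
56,male,0.00603919
57,male,0.00659945
58,male,0.00721517
59,male,0.00789182
60,male,0.00863537
61,male,0.00945238
62,male,0.01035
63,male,0.0113362
64,male,0.0124195
65,male,0.0136094
66,male,0.0149163
67,male,0.0163514
68,male,0.0179271
69,male,0.0196569
70,male,0.0215555
71,male,0.0236392
72,male,0.0259254
73,male,0.0284332
74,male,0.0311835
75,male,0.034199
76,male,0.0375041
77,male,0.0411255
78,male,0.0450921
79,male,0.0494351
80,male,0.0541881
81,male,0.0593873
82,male,0.0650717
83,male,0.071283
84,male,0.0780656
85,male,0.0854671
86,male,0.0935375
87,male,0.10233
88,male,0.1119
89,male,0.122307
90,male,0.13361
91,male,0.145871
92,male,0.159154
93,male,0.173522
94,male,0.189039
95,male,0.205766
96,male,0.223763
97,male,0.243082
98,male,0.263772
99,male,0.285872
100,male,0.309409
101,male,0.334397
102,male,0.360833
103,male,0.388693
104,male,0.417929
105,male,0.448468
106,male,0.480204
107,male,0.512998
108,male,0.546677
109,male,0.58103
110,male,1
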
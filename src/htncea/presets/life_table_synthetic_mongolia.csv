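age,qx
40,0.0022447841986149575
41,0.0024436913463374843
42,0.0026601998670463534
43,0.002895862959949702
44,0.003152370076913491
45,0.0034315587255211444
46,0.0037354272667613486
47,0.004066148785935475
48,0.004426086120588368
49,0.0048178081346130774
50,0.005244107333131964
51,0.00570801891823991
52,0.006212841391147861
53,0.006762158811580599
54,0.0073598648303440095
55,0.008010188615639069
56,0.008717722797767502
57,0.009487453560131032
58,0.01032479300659117
59,0.01123561393599637
60,0.012226287153602411
61,0.013303721445720451
62,0.01447540633765998
63,0.015749457745203754
64,0.017134666615654437
65,0.018640550634977604
66,0.020277409051615458
67,0.02205638063385884
68,0.023989504734725497
69,0.026089785384338038
70,0.02837125826281195
71,0.03084906032432455
72,0.03353950174270526
73,0.036460139727580665
74,0.03962985361447258
75,0.04306892045856492
76,0.04679909015602646
77,0.0508436588743697
78,0.0552275392895889
79,0.059977325797807235
80,0.06512135248783402
81,0.07068974122346983
82,0.07671443668607736
83,0.08322922466511651
84,0.09026972925457444
85,0.09787338391603084
86,0.10607937060685113
87,0.11492852035102064
88,0.12446316776207333
89,0.1347269511310918
90,0.14576454879560274
91,0.15762134164649444
92,0.1703429908631825
93,0.1839749193626573
94,0.19856168509672667
95,0.21414623434834212
96,0.23076902370363284
97,0.2484670005812306
98,0.2672724342843492
99,0.28721159273173547
100,0.3083032645720133
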
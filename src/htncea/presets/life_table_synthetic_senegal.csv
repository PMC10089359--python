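age,qx
40,0.0013474758402045595
41,0.001466932221487749
42,0.0015969701757324595
43,0.0017385254609585399
44,0.0018926162962084048
45,0.0020603505743013173
46,0.0022429336954696844
47,0.0024416770734501103
48,0.0026580073695411377
49,0.002893476514294835
50,0.0031497725809075394
51,0.003428731578987043
52,0.0037323502422089705
53,0.004062799888406077
54,0.00442244143584003
55,0.004813841664755958
56,0.005239790818767798
57,0.005703321646107207
58,0.006207729986221988
59,0.006756597012526733
60,0.0073538132471747675
61,0.008003604468383219
62,0.008710559634923953
63,0.009479660955652225
64,0.010316316234125544
65,0.011226393619123254
66,0.012216258890809684
67,0.013292815408923464
68,0.014463546843136776
69,0.015736562795935383
70,0.017120647414223145
71,0.01862531106639176
72,0.020260845135718797
73,0.02203837994735136
74,0.023969945803286596
75,0.02606853704593104
76,0.028348179003965135
77,0.030823997592067998
78,0.03351229123591204
79,0.03643060467275161
80,0.03959780403254587
81,0.04303415243116626
82,0.0467613851017451
83,0.050802782848188954
84,0.055183242321571346
85,0.05992934129057903
86,0.06506939669637879
87,0.07063351284527808
88,0.07665361659484382
89,0.08316347582696226
90,0.09019869687221516
91,0.09779669585340112
92,0.10599663815439897
93,0.1148393394001076
94,0.12436712046552278
95,0.13462360813569152
96,0.14565347214097002
97,0.15750208843271374
98,0.17021511779641785
99,0.18383798829276876
100,0.19841526966276102
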
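age,qx
40,0.002214886913585512
41,0.0024111481075536068
42,0.00262477712608733
43,0.0028573066692434423
44,0.0031104039118535765
45,0.00338588215636626
46,0.003685713468370766
47,0.004012042372587676
48,0.004367200692295681
49,0.004753723620494199
50,0.005174367116537515
51,0.00563212672746205
52,0.006130257938689043
53,0.006672298164130841
54,0.007262090490839701
55,0.007903809298073439
56,0.008601987874829353
57,0.009361548163297484
58,0.010187832758044801
59,0.011086639291729816
60,0.012064257337384143
61,0.01312750795430706
62,0.014283785998846832
63,0.015541105312128267
64,0.016908146883333086
65,0.018394310068538866
66,0.020009766920265792
67,0.021765519650513876
68,0.023673461208702284
69,0.02574643890383599
70,0.027998320935446963
71,0.03044406561810631
72,0.033099792987006604
73,0.03598285835433224
74,0.03911192724457824
75,0.04250705096798901
76,0.04618974189082359
77,0.05018304722482947
78,0.05451161988142539
79,0.05920178461371861
80,0.064281597296594
81,0.06978089476674154
82,0.07573133215603811
83,0.0821664040992709
84,0.08912144557808244
85,0.09663360747640382
86,0.10474180117036369
87,0.11348660566333824
88,0.12291012991513794
89,0.1330558221207616
90,0.14396821679481442
91,0.15569260964977372
92,0.16827464947068027
93,0.18175983555312003
94,0.19619290887307228
95,0.2116171251069977
96,0.22807339805532045
97,0.24559930310763667
98,0.2642279323185962
99,0.28398659566310247
100,0.30489536735606826
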
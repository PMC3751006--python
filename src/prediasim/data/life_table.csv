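age,qx
20,0.0006806803651763227
21,0.0006976743857284307
22,0.0007162655131943696
23,0.0007366038104750228
24,0.000758853433562745
25,0.0007831939537689125
26,0.0008098218037442262
27,0.0008389518588313161
28,0.0008708191663537868
29,0.0009056808366068037
30,0.0009438181105841936
31,0.0009855386208520445
32,0.0010311788634884689
33,0.0010811069006404495
34,0.0011357253150334756
35,0.0011954744397093542
36,0.0012608358883690052
37,0.0013323364139937732
38,0.0014105521258988007
39,0.0014961130980705173
40,0.0015897084045658483
41,0.0016920916209119952
42,0.001804086833874341
43,0.0019265952056591873
44,0.0020606021426101684
45,0.0022071851227609685
46,0.002367522241236819
47,0.0025429015374643926
48,0.0027347311734751134
49,0.002944550538280022
50,0.0031740423593581424
51,0.0034250459087463714
52,0.0036995713980454425
53,0.003999815663846107
54,0.004328179252630626
55,0.004687285022072829
56,0.005079998383810569
57,0.005509449321135729
58,0.005979056323552112
59,0.006492552388682626
60,0.00705401325042021
61,0.007667888000326695
62,0.008339032276859726
63,0.00907274420375348
64,0.009874803264440235
65,0.0107515123033175
66,0.011709742846404914
67,0.012756983932818655
68,0.013901394643716092
69,0.0151518605059483
70,0.016518053932439214
71,0.01801049883888106
72,0.01964063954503459
73,0.021420914026780036
74,0.02336483152975788
75,0.02548705448424271
76,0.027803484570639192
77,0.03033135267199083
78,0.033089312309911856
79,0.03609753598854604
80,0.03937781366201054
81,0.04295365228813375
82,0.04685037512826362
83,0.05109521909199666
84,0.05571742799873858
85,0.06074833912653499
86,0.06622145983384498
87,0.07217253036331406
88,0.07863956816023832
89,0.08566288815584588
90,0.09328509247272865
91,0.10155102190647336
92,0.11050766032904458
93,0.12020398185878345
94,0.13069072927262726
95,0.14202011073597987
96,0.15424540055047675
97,0.16742042834871562
98,0.18159894010564004
99,0.19683381363125385
100,0.21317611104248935
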
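age,qx
0,0.00020317935627833794
1,0.00020358005592391315
2,0.00020403094064858074
3,0.0002045382957867048
4,0.00020510919386051985
5,0.00020575159316638114
6,0.0002064744487089154
7,0.00020728783702661513
8,0.00020820309665015024
9,0.00020923298615005415
10,0.0002103918619766887
11,0.0002116958785701728
12,0.00021316321352948808
13,0.0002148143209768083
14,0.00021667221664878333
15,0.000218762798685046
16,0.0002211152085835888
17,0.00022376223735121048
18,0.0002267407825046197
19,0.0002300923622886586
20,0.00023386369426980913
21,0.0002381073463632033
22,0.0002428824693538889
23,0.0002482556211094167
24,0.0002543016939524634
25,0.0002611049580959479
26,0.000268760235654697
27,0.00027737422155793556
28,0.0002870669697244699
29,0.00029797356515470774
30,0.0003102460051626066
31,0.00032405531587087477
32,0.0003395939333386
33,0.0003570783823472201
34,0.00037675228997535726
35,0.000398889775702127
36,0.0004237992649572808
37,0.00045182777884655856
38,0.00048336575930751913
39,0.000518852496264266
40,0.0005587822315638036
41,0.0006037110236722931
42,0.0006542644674240039
43,0.0007111463746604096
44,0.00077514853451921
45,0.0008471616865871612
46,0.000928187856279572
47,0.0010193542198452255
48,0.0011219286865024047
49,0.0012373374076218857
50,0.0013671844477934902
51,0.0015132738802982049
52,0.001677634600204092
53,0.0018625481822633905
54,0.00207058014827477
55,0.002304615049830039
56,0.0025678958176292843
57,0.0028640678780013085
58,0.003197228591074519
59,0.003571982623235548
60,0.003993503929059394
61,0.004467605084552351
62,0.005000814783883367
63,0.005600464385040027
64,0.006274784464886052
65,0.007033012419250251
66,0.007885512216592283
67,0.00884390748124142
68,0.009921229139834509
69,0.011132078906612275
70,0.012492809902069912
71,0.01402172568523985
72,0.015739298919926314
73,0.01766841077329795
74,0.019834611940887314
75,0.02226640587947304
76,0.024995554376452622
77,0.028057404951486453
78,0.03149123872488235
79,0.03534063623854988
80,0.039653857208913124
81,0.044484228243648505
82,0.04989053006870936
83,0.05593737267864729
84,0.06269554291971191
85,0.07024230421149391
86,0.07866162227778528
87,0.08804428377052376
88,0.09848786644131191
89,0.11009651000969944
90,0.12298042616064164
91,0.13725507439377616
92,0.15303991819262797
93,0.17045666395897696
94,0.18962687459396
95,0.21066884232724625
96,0.23369360397992
97,0.25879998978983965
98,0.28606861875504663
99,0.31555479473694015
100,0.3472803247699626
101,0.38122438101053846
102,0.4173136668278252
103,0.4554123298009496
104,0.4953122892654347
105,0.536724904838819
106,0.5792751839315151
107,0.6224999724811551
108,0.6658517351584
109,0.708709528660577
110,1.0
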
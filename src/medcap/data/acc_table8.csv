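ID,OPTZ,TL,TR,IA,Loss,ACC,Epochs,Training Time (s),Test Time (s)
97,Adam,0,1,0,0.7686,0.7215,16,2994,120
98,AdamW,0,1,0,0.7551,0.7223,9,1724,121
99,Adadelta,0,1,0,0.7416,0.7334,9,1728,118
100,Adafactor,0,1,0,0.7381,0.7289,7,1358,120
101,Adam,0,1,1,0.7961,0.7069,16,3174,121
102,AdamW,0,1,1,0.7709,0.7104,6,1244,134
103,Adadelta,0,1,1,0.7614,0.7154,6,1200,124
104,Adafactor,0,1,1,0.7687,0.7131,4,799,121
105,Adam,1,0,0,0.7521,0.7235,12,2342,124
106,AdamW,1,0,0,0.7493,0.7298,4,821,134
107,Adadelta,1,0,0,0.7416,0.7310,4,804,131
108,Adafactor,1,0,0,0.7381,0.7313,6,1208,132
109,Adam,1,0,1,0.7825,0.7306,20,4983,171
110,AdamW,1,0,1,0.7013,0.7449,4,870,139
111,Adadelta,1,0,1,0.6895,0.7499,6,1238,133
112,Adafactor,1,0,1,0.6848,0.7479,4,826,132
113,Adam,1,1,0,0.7112,0.7400,12,2371,133
114,AdamW,1,1,0,0.7237,0.7362,4,1003,124
115,Adadelta,1,1,0,0.7209,0.7354,4,1232,278
116,Adafactor,1,1,0,0.7134,0.7366,4,1483,274
117,Adam,1,1,1,0.6928,0.7359,20,3613,125
118,AdamW,1,1,1,0.6896,0.7413,4,772,141
119,Adadelta,1,1,1,0.6958,0.7393,6,1186,133
120,Adafactor,1,1,1,0.6816,0.7463,8,1599,142
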
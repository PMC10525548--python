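ID,OPTZ,TL,TR,IA,Loss,ACC,Epochs,Training Time (s),Test Time (s)
73,Adam,0,1,0,0.7734,0.7056,16,9480,310
74,AdamW,0,1,0,0.7534,0.7166,7,3384,158
75,Adadelta,0,1,0,0.7375,0.7252,11,5194,150
76,Adafactor,0,1,0,0.7231,0.7242,6,2831,150
77,Adam,0,1,1,0.8118,0.7126,12,5693,150
78,AdamW,0,1,1,0.7517,0.7258,16,7615,152
79,Adadelta,0,1,1,0.7382,0.7318,5,2336,150
80,Adafactor,0,1,1,0.7266,0.7273,6,2805,151
81,Adam,1,0,0,0.6648,0.7510,10,4685,152
82,AdamW,1,0,0,0.6530,0.7485,4,1887,158
83,Adadelta,1,0,0,0.6530,0.7483,8,3879,156
84,Adafactor,1,0,0,0.6485,0.7503,5,2459,166
85,Adam,1,0,1,0.6276,0.7628,18,8930,163
86,AdamW,1,0,1,0.6509,0.7456,4,2014,172
87,Adadelta,1,0,1,0.6325,0.7525,10,5040,171
88,Adafactor,1,0,1,0.6158,0.7607,14,7091,176
89,Adam,1,1,0,0.6659,0.7558,11,5467,168
90,AdamW,1,1,0,0.6608,0.7580,7,3410,240
91,Adadelta,1,1,0,0.6787,0.7538,4,3495,153
92,Adafactor,1,1,0,0.6784,0.7477,7,3179,163
93,Adam,1,1,1,0.6608,0.7586,10,4369,150
94,AdamW,1,1,1,0.6380,0.7552,13,6118,170
95,Adadelta,1,1,1,0.6307,0.7564,10,6210,174
96,Adafactor,1,1,1,0.6224,0.7593,5,2512,177
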
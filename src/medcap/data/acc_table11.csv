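ID,OPTZ,TL,TR,IA,Loss,ACC,Epochs,Training Time (s),Test Time (s)
169,Adam,0,1,0,0.9017,0.6775,16,1209,76
170,AdamW,0,1,0,0.9028,0.6704,7,552,79
171,Adadelta,0,1,0,0.8984,0.6734,4,327,79
172,Adafactor,0,1,0,0.9001,0.6773,7,555,77
173,Adam,0,1,1,0.9104,0.6603,10,840,74
174,AdamW,0,1,1,0.9119,0.6839,7,592,81
175,Adadelta,0,1,1,0.9063,0.6779,9,833,84
176,Adafactor,0,1,1,0.8998,0.6809,5,467,83
177,Adam,1,0,0,0.8022,0.7108,11,935,85
178,AdamW,1,0,0,0.7965,0.7183,4,343,82
179,Adadelta,1,0,0,0.7940,0.7173,6,517,85
180,Adafactor,1,0,0,0.7759,0.7229,7,596,84
181,Adam,1,0,1,0.7684,0.7125,14,1304,85
182,AdamW,1,0,1,0.7910,0.7196,4,384,88
183,Adadelta,1,0,1,0.7795,0.7186,4,384,90
184,Adafactor,1,0,1,0.7715,0.7203,4,383,89
185,Adam,1,1,0,0.7996,0.7118,11,1016,104
186,AdamW,1,1,0,0.7855,0.7225,4,428,111
187,Adadelta,1,1,0,0.7622,0.7306,4,431,103
188,Adafactor,1,1,0,0.7712,0.7238,7,639,89
189,Adam,1,1,1,0.7532,0.7150,14,1350,90
190,AdamW,1,1,1,0.7434,0.7282,7,794,112
191,Adadelta,1,1,1,0.7261,0.7345,4,400,93
192,Adafactor,1,1,1,0.7353,0.7253,10,1166,113
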
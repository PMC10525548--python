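ID,OPTZ,TL,TR,IA,Loss,ACC,Epochs,Training Time (s),Test Time (s)
121,Adam,0,1,0,0.8028,0.7109,20,2202,129
122,AdamW,0,1,0,0.7700,0.7125,4,472,131
123,Adadelta,0,1,0,0.7584,0.7145,7,825,132
124,Adafactor,0,1,0,0.7457,0.7319,10,1170,131
125,Adam,0,1,1,0.8109,0.6992,17,2066,133
126,AdamW,0,1,1,0.8084,0.7054,4,487,132
127,Adadelta,0,1,1,0.7991,0.7070,9,1199,182
128,Adafactor,0,1,1,0.7926,0.6997,8,1056,167
129,Adam,1,0,0,0.7521,0.7283,12,1490,164
130,AdamW,1,0,0,0.7507,0.7300,4,500,169
131,Adadelta,1,0,0,0.7498,0.7358,6,749,165
132,Adafactor,1,0,0,0.7371,0.7315,5,635,179
133,Adam,1,0,1,0.7435,0.7213,13,1724,189
134,AdamW,1,0,1,0.7246,0.7315,12,1599,174
135,Adadelta,1,0,1,0.7044,0.7425,7,934,180
136,Adafactor,1,0,1,0.7118,0.7472,8,1059,187
137,Adam,1,1,0,0.7869,0.7324,12,1565,192
138,AdamW,1,1,0,0.7718,0.7217,4,528,182
139,Adadelta,1,1,0,0.7571,0.7285,8,1075,198
140,Adafactor,1,1,0,0.7541,0.7276,7,1478,216
141,Adam,1,1,1,0.7626,0.7210,12,2631,229
142,AdamW,1,1,1,0.7178,0.7337,12,2519,227
143,Adadelta,1,1,1,0.7238,0.7267,4,739,210
144,Adafactor,1,1,1,0.7320,0.7249,4,858,222
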
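ID,OPTZ,TL,TR,IA,Loss,ACC,Epochs,Training Time (s),Test Time (s)
145,Adam,0,1,0,0.8118,0.7066,12,3164,269
146,AdamW,0,1,0,0.8171,0.6901,7,1887,267
147,Adadelta,0,1,0,0.8048,0.6975,7,1890,272
148,Adafactor,0,1,0,0.7941,0.7117,5,1369,283
149,Adam,0,1,1,0.8011,0.7165,15,4679,264
150,AdamW,0,1,1,0.8145,0.6922,4,1149,307
151,Adadelta,0,1,1,0.8067,0.6940,6,1744,343
152,Adafactor,0,1,1,0.7871,0.7076,8,3213,456
153,Adam,1,0,0,0.8422,0.6967,12,4939,455
154,AdamW,1,0,0,0.8247,0.6920,5,1838,418
155,Adadelta,1,0,0,0.8167,0.7019,11,4628,472
156,Adafactor,1,0,0,0.8269,0.6915,4,2113,547
157,Adam,1,0,1,0.8184,0.6886,16,8287,489
158,AdamW,1,0,1,0.7907,0.6997,11,4793,504
159,Adadelta,1,0,1,0.7863,0.7073,6,3332,1245
160,Adafactor,1,0,1,0.7823,0.7054,7,3881,1211
161,Adam,1,1,0,0.8214,0.6962,16,4131,255
162,AdamW,1,1,0,0.8192,0.7011,9,2375,271
163,Adadelta,1,1,0,0.8087,0.7122,4,1047,262
164,Adafactor,1,1,0,0.7982,0.7057,6,1576,260
165,Adam,1,1,1,0.8305,0.6823,17,4530,265
166,AdamW,1,1,1,0.8246,0.6848,4,1095,313
167,Adadelta,1,1,1,0.8146,0.6906,9,2500,320
168,Adafactor,1,1,1,0.8136,0.6923,4,1133,330
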
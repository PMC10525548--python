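ID,OPTZ,TL,TR,IA,Loss,ACC,Epochs,Training Time (s),Test Time (s)
1,Adam,0,1,0,0.7487,0.7276,20,6520,246
2,AdamW,0,1,0,0.7727,0.7205,6,1656,250
3,Adadelta,0,1,0,0.7601,0.7253,8,2185,248
4,Adafactor,0,1,0,0.7539,0.7275,7,1896,259
5,Adam,0,1,1,0.7894,0.7151,20,5662,249
6,AdamW,0,1,1,0.7461,0.7271,6,1706,281
7,Adadelta,0,1,1,0.7390,0.7279,6,1784,293
8,Adafactor,0,1,1,0.7199,0.7356,6,1812,314
9,Adam,1,0,0,0.7438,0.7443,10,2887,293
10,AdamW,1,0,0,0.7244,0.7406,4,1160,298
11,Adadelta,1,0,0,0.7223,0.7413,8,2345,306
12,Adafactor,1,0,0,0.7190,0.7446,5,1476,319
13,Adam,1,0,1,0.6907,0.7413,18,5463,334
14,AdamW,1,0,1,0.6890,0.7483,4,1454,400
15,Adadelta,1,0,1,0.6818,0.7549,10,3400,357
16,Adafactor,1,0,1,0.6807,0.7532,7,3010,443
17,Adam,1,1,0,0.7519,0.7337,11,4778,345
18,AdamW,1,1,0,0.7534,0.7439,4,1203,329
19,Adadelta,1,1,0,0.7408,0.7449,5,1540,346
20,Adafactor,1,1,0,0.7190,0.7610,6,2205,420
21,Adam,1,1,1,0.7236,0.7262,18,6640,424
22,AdamW,1,1,1,0.7349,0.7242,4,1530,436
23,Adadelta,1,1,1,0.7059,0.7343,8,2733,366
24,Adafactor,1,1,1,0.7044,0.7318,4,1649,433
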
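ID,OPTZ,TL,TR,IA,Loss,ACC,Epochs,Training Time (s),Test Time (s)
25,Adam,0,1,0,0.8128,0.7020,20,7844,293
26,AdamW,0,1,0,0.8027,0.7113,4,1654,385
27,Adadelta,0,1,0,0.7894,0.7174,10,3999,294
28,Adafactor,0,1,0,0.7840,0.7127,7,2815,308
29,Adam,0,1,1,0.8791,0.6868,11,4493,299
30,AdamW,0,1,1,0.8525,0.6929,5,2059,332
31,Adadelta,0,1,1,0.8480,0.6908,10,4116,355
32,Adafactor,0,1,1,0.8499,0.6919,6,2428,337
33,Adam,1,0,0,0.7817,0.7277,15,5974,338
34,AdamW,1,0,0,0.7539,0.7278,11,4395,318
35,Adadelta,1,0,0,0.7524,0.7263,7,2912,366
36,Adafactor,1,0,0,0.7413,0.7359,9,3771,452
37,Adam,1,0,1,0.7865,0.7151,18,7519,382
38,AdamW,1,0,1,0.7712,0.7248,6,2548,372
39,Adadelta,1,0,1,0.7722,0.7228,7,2957,361
40,Adafactor,1,0,1,0.7533,0.7311,11,4672,384
41,Adam,1,1,0,0.7424,0.7237,19,7932,381
42,AdamW,1,1,0,0.7593,0.7124,4,1647,334
43,Adadelta,1,1,0,0.7469,0.7136,7,2891,359
44,Adafactor,1,1,0,0.7271,0.7246,8,3645,1042
45,Adam,1,1,1,0.7815,0.7033,20,9948,396
46,AdamW,1,1,1,0.7629,0.7214,4,1648,339
47,Adadelta,1,1,1,0.7523,0.7234,6,2713,453
48,Adafactor,1,1,1,0.7425,0.7298,11,5785,489
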
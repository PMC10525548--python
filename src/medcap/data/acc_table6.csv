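ID,OPTZ,TL,TR,IA,Loss,ACC,Epochs,Training Time (s),Test Time (s)
49,Adam,0,1,0,0.8557,0.6914,16,7587,466
50,AdamW,0,1,0,0.8530,0.6980,5,2427,479
51,Adadelta,0,1,0,0.8526,0.6900,5,2418,495
52,Adafactor,0,1,0,0.8356,0.7011,8,3887,482
53,Adam,0,1,1,0.8414,0.7001,18,8774,490
54,AdamW,0,1,1,0.8509,0.6891,4,2005,551
55,Adadelta,0,1,1,0.8475,0.6969,8,3699,537
56,Adafactor,0,1,1,0.8459,0.6949,5,2494,523
57,Adam,1,0,0,0.8125,0.7084,11,5433,531
58,AdamW,1,0,0,0.8115,0.7095,4,1967,537
59,Adadelta,1,0,0,0.7938,0.7105,7,3798,674
60,Adafactor,1,0,0,0.7849,0.7173,6,3864,765
61,Adam,1,0,1,0.8122,0.7065,15,10067,822
62,AdamW,1,0,1,0.7857,0.7089,6,3495,707
63,Adadelta,1,0,1,0.7780,0.7137,6,4172,832
64,Adafactor,1,0,1,0.7734,0.7081,5,3401,862
65,Adam,1,1,0,0.7838,0.7061,12,7191,768
66,AdamW,1,1,0,0.8015,0.7141,7,3520,572
67,Adadelta,1,1,0,0.8002,0.7121,4,2210,603
68,Adafactor,1,1,0,0.7813,0.7210,7,4260,768
69,Adam,1,1,1,0.8082,0.7021,11,6600,691
70,AdamW,1,1,1,0.8155,0.7010,5,2702,629
71,Adadelta,1,1,1,0.7998,0.7058,6,3095,609
72,Adafactor,1,1,1,0.7875,0.7134,10,6359,821
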
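CNN,mu,sigma,Min,Max,mu-sigma,mu+sigma
DenseNet201,0.7365,0.0114,0.7151,0.7610,0.7250,0.7479
ResNet152V2,0.7154,0.0138,0.6868,0.7359,0.7016,0.7292
NASNetLarge,0.7050,0.0085,0.6891,0.7210,0.6965,0.7135
VGG19,0.7431,0.0167,0.7056,0.7628,0.7264,0.7598
Xception,0.7313,0.0116,0.7069,0.7499,0.7197,0.7429
InceptionV3,0.7236,0.0124,0.6992,0.7472,0.7111,0.7360
InceptionResNetV2,0.6985,0.0089,0.6823,0.7165,0.6896,0.7074
MobileNetV2,0.7056,0.0225,0.6603,0.7345,0.6831,0.7281
Global,0.7199,0.0206,0.6603,0.7628,0.6992,0.7404
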
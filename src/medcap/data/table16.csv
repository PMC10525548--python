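Class,P,N,TP,FP,TN,FN,TPR,TNR,PPV,NPV,ACC,F1
chest,54,230,39,18,212,15,0.72,0.92,0.68,0.93,0.88,0.70
abdomen,52,232,47,78,154,5,0.90,0.66,0.38,0.97,0.71,0.53
artery,35,249,24,7,242,11,0.69,0.97,0.77,0.96,0.94,0.73
lung,36,248,16,17,187,20,0.44,0.92,0.48,0.90,0.85,0.46
lobe,25,259,1,2,257,24,0.04,0.99,0.33,0.91,0.91,0.07
head,15,269,1,1,268,14,0.07,1.00,0.50,0.95,0.95,0.12
liver,10,274,0,0,274,10,0.00,1.00,-,0.96,0.96,-
pelvi,2,282,2,11,271,0,1.00,0.96,0.15,1.00,0.96,0.27
bone,11,273,6,12,261,5,0.55,0.96,0.33,0.98,0.94,0.41
pulmonary,7,277,0,0,277,7,0.00,1.00,-,0.98,0.98,-
aortic,5,279,0,0,279,5,0.00,1.00,-,0.98,0.98,-
vein,11,273,0,0,273,11,0.00,1.00,-,0.96,0.96,-
hip,4,280,1,0,280,3,0.25,1.00,1.00,0.99,0.99,0.40
neck,10,274,0,0,274,10,0.00,1.00,-,0.96,0.96,-
femoral,7,277,1,0,277,6,0.14,1.00,1.00,0.98,0.98,0.25
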
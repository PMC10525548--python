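Class,P,N,TP,FP,TN,FN,TPR,TNR,PPV,NPV,ACC,F1
nodule,51,233,30,12,221,21,0.59,0.95,0.71,0.91,0.88,0.65
hepatic,45,239,5,8,231,40,0.11,0.97,0.38,0.85,0.83,0.17
aneurysm,30,254,15,15,239,15,0.50,0.94,0.50,0.94,0.89,0.50
fracture,34,250,30,3,247,4,0.88,0.99,0.91,0.98,0.98,0.90
normal,32,252,21,4,248,11,0.66,0.98,0.84,0.96,0.95,0.74
tumor,18,266,9,9,257,9,0.50,0.97,0.50,0.97,0.94,0.50
pancreatic,22,262,15,32,230,7,0.68,0.88,0.32,0.97,0.86,0.43
effusion,20,264,0,6,258,20,0.00,0.98,0.00,0.93,0.91,-
cystic,19,265,9,56,209,10,0.47,0.79,0.14,0.95,0.77,0.21
hematoma,7,277,0,5,272,7,0.00,0.98,0.00,0.97,0.96,-
cyst,6,278,0,0,278,6,0.00,1.00,-,0.98,0.98,-
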
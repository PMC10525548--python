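Class,P,N,TP,FP,TN,FN,TPR,TNR,PPV,NPV,ACC,F1
ct,123,161,108,44,117,15,0.88,0.73,0.71,0.89,0.79,0.79
radiograph,45,239,32,2,237,13,0.71,0.99,0.94,0.95,0.95,0.81
scan,51,233,26,20,213,25,0.51,0.91,0.57,0.89,0.84,0.54
tomography,25,259,0,8,251,25,0.00,0.97,0.00,0.91,0.88,-
xray,11,273,11,12,261,0,1.00,0.96,0.48,1.00,0.96,0.65
angiogram,11,273,9,10,263,2,0.82,0.96,0.47,0.99,0.96,0.60
angiography,10,274,0,1,273,10,0.00,1.00,0.00,0.96,0.96,-
abdominal,5,279,0,0,279,5,0.00,1.00,-,0.98,0.98,-
contrast,3,281,0,1,280,3,0.00,1.00,0.00,0.99,0.99,-
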
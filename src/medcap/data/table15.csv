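Class,chest,abdomen,artery,lung,lobe,head,liver,pelvi,bone,pulmonary,aortic,vein,hip,neck,femoral
chest,39,3,0,10,1,0,0,0,1,0,0,0,0,0,0
abdomen,0,47,2,2,0,0,0,0,1,0,0,0,0,0,0
artery,1,10,24,0,0,0,0,0,0,0,0,0,0,0,0
lung,12,6,2,16,0,0,0,0,0,0,0,0,0,0,0
lobe,0,22,1,1,1,0,0,0,0,0,0,0,0,0,0
head,0,14,0,0,0,1,0,0,0,0,0,0,0,0,0
liver,0,10,0,0,0,0,0,0,0,0,0,0,0,0,0
pelvi,0,0,0,0,0,0,0,2,0,0,0,0,0,0,0
bone,2,1,0,0,0,0,0,2,6,0,0,0,0,0,0
pulmonary,2,0,1,4,0,0,0,0,0,0,0,0,0,0,0
aortic,0,3,1,0,1,0,0,0,0,0,0,0,0,0,0
vein,0,9,0,0,0,1,0,0,1,0,0,0,0,0,0
hip,0,0,0,0,0,0,0,2,1,0,0,0,1,0,0
neck,1,0,0,0,0,0,0,6,3,0,0,0,0,0,0
femoral,0,0,0,0,0,0,0,1,5,0,0,0,0,0,1
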
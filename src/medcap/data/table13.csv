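Class,ct,radiograph,scan,tomography,xray,angiogram,angiography,abdominal,contrast
ct,108,2,10,3,0,0,0,0,0
radiograph,1,32,0,0,12,0,0,0,0
scan,19,0,26,5,0,0,0,0,1
tomography,16,0,9,0,0,0,0,0,0
xray,0,0,0,0,11,0,0,0,0
angiogram,1,0,0,0,0,9,1,0,0
angiography,3,0,0,0,0,7,0,0,0
abdominal,4,0,1,0,0,0,0,0,0
contrast,0,0,0,0,0,3,0,0,0
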
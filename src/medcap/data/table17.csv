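Class,nodule,hepatic,aneurysm,fracture,normal,tumor,pancreatic,effusion,cystic,hematoma,cyst
nodule,30,3,2,0,0,4,0,4,8,0,0
hepatic,0,5,1,1,0,0,16,0,22,0,0
aneurysm,1,1,15,0,1,0,3,0,8,1,0
fracture,0,0,0,30,3,0,0,0,1,0,0
normal,0,0,9,1,21,0,0,0,1,0,0
tumor,1,1,0,1,0,9,2,0,3,1,0
pancreatic,0,2,0,0,0,0,15,0,2,3,0
effusion,10,0,1,0,0,5,0,0,4,0,0
cystic,0,0,2,0,0,0,6,2,9,0,0
hematoma,0,1,0,0,0,0,3,0,3,0,0
cyst,0,0,0,0,0,0,2,0,4,0,0
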
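patient_id,group,r,l,a,p,s,i
L1,liver,8.6,9.3,2.5,8.7,4.0,12.0
L2,liver,2.0,2.0,0.0,11.0,7.6,5.9
L3,liver,6.4,0.0,5.5,3.5,4.1,6.4
L4,liver,0.0,0.0,0.0,0.0,3.6,0.0
L5,liver,7.8,5.0,20.7,0.0,4.6,5.0
L6,liver,1.9,1.0,0.0,14.5,15.0,2.6
P1,pancreatic,3.1,2.8,5.5,3.1,1.7,7.2
P2,pancreatic,0.0,4.4,3.7,3.7,1.4,0.0
P3,pancreatic,0.0,0.0,12.0,0.0,0.0,0.0
P4,pancreatic,3.7,0.0,0.0,4.0,1.7,3.5
P5,pancreatic,0.0,3.5,4.5,0.0,1.3,4.1
P6,pancreatic,3.7,4.7,4.5,0.0,1.8,4.5
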
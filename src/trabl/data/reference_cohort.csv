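specimen,age,sex,type,PostInf,Inf,AntInf,AntSup,PostSup,Med
A,68,F,IIIb,0,8,58,22,28,0
B,50,F,IIIb,18,55,83,35,82,25
C,79,F,IIIb,28,18,41,18,29,34
D,66,M,IIIb,23,8,69,53,92,3
E,70,M,IIIb,29,17,56,22,50,19
F,66,M,IIIb,42,0,0,19,74,0
G,51,M,IIIb,14,2,0,12,61,0
H,60,F,IIIb,10,9,14,8,23,2
I,77,M,IIIb,27,24,7,3,66,86
J,68,F,IIIb,17,1,20,46,86,0
K,69,M,IIIb,14,9,10,17,62,17
L,59,F,IIc,10,2,0,5,25,12
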
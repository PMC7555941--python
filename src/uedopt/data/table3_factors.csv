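no,name,level1,level2,level3
A,conv1_Kernel size,3,5,7
B,conv1_Filter,4,6,12
C,conv1_Stride,1,2,
D,conv1_Padding,0,1,
E,conv2_Kernel size,3,5,7
F,conv2_Filter,8,16,32
G,conv2_Stride,1,2,
H,conv2_Padding,0,1,
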
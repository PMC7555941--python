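run,"conv1_Kernel size","conv1_Filter","conv1_Stride","conv1_Padding","conv2_Kernel size","conv2_Filter","conv2_Stride","conv2_Padding"
1,5,12,1,0,3,32,1,0
2,5,12,1,1,3,32,2,1
3,3,4,1,0,7,8,2,1
4,3,12,1,0,3,16,2,0
5,7,6,2,0,7,8,1,0
6,3,12,1,1,5,16,1,1
7,7,6,1,0,7,32,2,0
8,7,4,2,1,7,32,1,0
9,3,6,2,0,5,16,2,0
10,5,4,1,1,7,32,2,1
11,5,4,1,1,5,8,2,1
12,5,6,1,0,3,16,1,1
13,7,4,2,0,5,8,1,0
14,5,12,2,1,5,8,2,1
15,3,4,2,1,3,8,2,0
16,7,6,2,1,3,8,1,0
17,3,6,2,0,5,16,1,0
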
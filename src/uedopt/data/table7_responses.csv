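run,"conv1_Kernel size","conv1_Filter","conv1_Stride","conv1_Padding","conv2_Kernel size","conv2_Filter","conv2_Stride","conv2_Padding",Y1,Y2,Y3,Y_avg
1,5,12,1,0,3,32,1,0,82.81,82.81,81.12,82.24
2,5,12,1,1,3,32,2,1,82.55,83.99,83.65,83.40
3,3,4,1,0,7,8,2,1,77.20,82.55,82.47,80.74
4,3,12,1,0,3,16,2,0,83.27,82.89,82.72,82.96
5,7,6,2,0,7,8,1,0,72.73,82.39,77.83,77.65
6,3,12,1,1,5,16,1,1,82.93,74.55,82.72,80.07
7,7,6,1,0,7,32,2,0,83.27,81.84,83.19,82.76
8,7,4,2,1,7,32,1,0,82.30,80.83,83.48,82.20
9,3,6,2,0,5,16,2,0,82.01,82.17,83.86,82.68
10,5,4,1,1,7,32,2,1,82.34,83.06,83.27,82.89
11,5,4,1,1,5,8,2,1,82.34,81.04,75.94,79.77
12,5,6,1,0,3,16,1,1,83.35,82.09,75.43,80.29
13,7,4,2,0,5,8,1,0,77.71,82.39,77.45,79.18
14,5,12,2,1,5,8,2,1,79.39,83.02,83.10,81.84
15,3,4,2,1,3,8,2,0,82.13,82.89,83.40,82.81
16,7,6,2,1,3,8,1,0,82.60,83.65,81.88,82.71
17,3,6,2,0,5,16,1,0,75.05,81.88,81.96,79.63
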
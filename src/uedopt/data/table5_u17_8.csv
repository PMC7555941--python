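run,c1,c2,c3,c4,c5,c6,c7,c8
1,1,5,6,8,8,9,17,17
2,2,12,17,5,15,5,10,8
3,3,10,4,15,4,6,6,4
4,4,2,9,12,14,16,3,11
5,5,16,12,2,5,12,14,13
6,6,6,10,1,10,2,4,3
7,7,13,1,17,11,14,12,9
8,8,4,16,9,1,15,11,5
9,9,15,5,10,17,3,7,15
10,10,7,2,4,3,10,1,12
11,11,8,11,14,16,11,16,2
12,12,1,13,16,6,4,9,14
13,13,14,7,6,7,17,8,1
14,14,17,15,13,9,8,2,7
15,15,3,3,3,13,7,13,6
16,16,11,8,11,2,1,15,10
17,17,9,14,7,12,13,5,16
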
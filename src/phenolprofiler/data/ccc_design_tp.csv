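run,role,x1_coded,x2_coded,x3_coded,x1_uncoded,x2_uncoded,x3_uncoded,response
1,factorial,-1,-1,-1,20,10,40,0.71
2,factorial,1,-1,-1,40,10,40,0.93
3,factorial,-1,1,-1,20,30,40,1.16
4,factorial,1,1,-1,40,30,40,1.04
5,factorial,-1,-1,1,20,10,60,0.84
6,factorial,1,-1,1,40,10,60,1.03
7,factorial,-1,1,1,20,30,60,1.27
8,factorial,1,1,1,40,30,60,1.21
9,axial,-1.68,0,0,13.2,20,50,1.11
10,axial,1.68,0,0,46.8,20,50,1.28
11,axial,0,-1.68,0,30,3.2,50,0.68
12,axial,0,1.68,0,30,36.8,50,1.23
13,axial,0,0,-1.68,30,20,33.2,0.89
14,axial,0,0,1.68,30,20,66.8,1.13
15,center,0,0,0,30,20,50,1.02
16,center,0,0,0,30,20,50,1.20
17,center,0,0,0,30,20,50,1.07
18,center,0,0,0,30,20,50,1.26
19,center,0,0,0,30,20,50,1.15
20,center,0,0,0,30,20,50,1.07
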
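patient,ns,tp,fp,latency_s,sensitivity_pct,delay_s,fp_per_hour
1,7,7,0,2.00,100.00,-4.00,0.00
2,3,1,0,0.00,33.33,-25.00,0.00
3,7,7,1,5.14,100.00,-0.86,0.03
4,4,4,0,10.25,100.00,4.25,0.00
5,5,5,0,18.80,100.00,12.80,0.00
6,10,1,0,80.00,10.00,74.00,0.00
7,3,3,0,11.00,100.00,5.00,0.00
8,5,4,0,0.50,80.00,-5.50,0.00
9,4,4,0,0.25,100.00,-5.75,0.00
10,7,5,0,1.60,71.43,-4.40,0.00
11,3,2,0,8.00,66.67,2.00,0.00
12,40,32,2,3.25,80.00,-2.75,0.08
13,12,10,5,11.40,83.33,5.40,0.15
14,8,3,0,0.00,37.50,-6.00,0.00
15,20,17,2,2.41,85.00,-3.59,0.05
16,10,7,0,5.57,70.00,-0.42,0.00
17,3,2,1,0.00,66.67,-6.00,0.05
18,6,5,3,4.00,83.33,-2.00,0.08
19,3,3,0,0.00,100.00,-6.00,0.00
20,8,7,1,2.71,87.50,-3.28,0.04
21,4,2,0,0.00,50.00,-6.00,0.00
22,3,3,0,0.00,100.00,-6.00,0.00
23,7,7,1,1.71,100.00,-4.28,0.04
24,16,15,0,1.20,93.75,-4.80,0.00
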
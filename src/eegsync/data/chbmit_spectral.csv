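patient,ns,tp,fp,latency_s,sensitivity_pct,delay_s,fp_per_hour
1,7,7,3,8.57,100.00,2.57,0.07
2,3,2,7,12.50,66.67,6.50,0.20
3,7,7,9,7.43,100.00,1.43,0.26
4,4,2,5,36.50,50.00,30.50,0.14
5,5,5,0,11.40,100.00,5.40,0.00
7,3,3,3,18.67,100.00,12.67,0.05
8,5,5,0,13.60,100.00,7.60,0.09
9,4,4,3,9.25,100.00,3.25,0.04
10,7,7,2,9.86,100.00,3.86,0.04
11,3,1,0,30.00,33.33,24.00,0.00
17,3,3,36,22.33,100.00,16.33,1.80
18,6,5,6,11.20,83.33,5.20,0.17
19,3,3,0,33.67,100.00,27.67,0.00
20,8,8,8,14.25,100.00,8.25,0.29
22,3,3,3,18.33,100.00,12.33,0.10
23,7,7,5,3.14,100.00,-2.86,0.19
24,16,16,9,12.31,100.00,6.31,0.42
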
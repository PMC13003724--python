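patient,age,sex,htn,dyslip,dm,cad,vasculitis,smoking,size_cm,tawss_bin,osi_bin,ecap_bin,rrt_bin,ilt_group,shape,status
1,51,M,yes,no,yes,no,no,yes,6.2,0-0.5,0.35-0.5,1.6-2,24-30,low,fusiform,ruptured
2,62,M,yes,yes,yes,no,no,yes,7,0-0.5,0.35-0.5,1.2-1.6,24-30,low,saccular,ruptured
3,61,M,yes,yes,yes,no,no,yes,9.3,0-0.5,0.35-0.5,1.6-2,24-30,low,fusiform,ruptured
4,31,M,yes,no,no,no,yes,yes,6,0-0.5,0.35-0.5,1.6-2,24-30,low,fusiform,impending
5,64,M,yes,yes,no,no,no,no,8.5,0-0.5,0.2-0.35,1.6-2,18-24,low,fusiform,ruptured
6,74,M,yes,no,no,yes,no,yes,6.2,0-0.5,0.35-0.5,1.6-2,18-24,low,fusiform,ruptured
7,54,M,yes,yes,yes,yes,no,yes,4.5,0-0.5,0.35-0.5,0.8-1.2,24-30,low,fusiform,ruptured
8,79,M,yes,yes,no,no,no,yes,10,0-0.5,0.35-0.5,0.8-1.2,18-24,low,fusiform,ruptured
9,73,M,yes,yes,yes,no,no,no,5.1,0.5-1,0.35-0.5,0.2-0.8,24-30,low,fusiform,ruptured
10,76,F,yes,no,no,no,no,no,6.1,0-0.5,0.35-0.5,1.6-2,24-30,low,fusiform,ruptured
11,80,M,no,yes,no,no,no,yes,9.9,0-0.5,0.35-0.5,1.6-2,24-30,low,fusiform,ruptured
12,43,F,yes,no,yes,no,no,no,5.3,0-0.5,0.2-0.35,1.6-2,24-30,low,saccular,ruptured
13,81,M,yes,yes,yes,no,no,yes,5.3,0-0.5,0.35-0.5,1.6-2,24-30,high,fusiform,ruptured
14,77,F,no,no,no,yes,yes,no,5.9,0-0.5,0.35-0.5,1.6-2,24-30,high,fusiform,ruptured
15,63,M,yes,yes,yes,no,no,yes,7,0-0.5,0.35-0.5,1.6-2,24-30,high,fusiform,ruptured
16,66,M,no,yes,yes,no,no,yes,9.5,0-0.5,0.35-0.5,1.6-2,24-30,high,fusiform,impending
17,93,M,yes,yes,yes,yes,no,yes,4.5,0-0.5,0.35-0.5,1.6-2,24-30,high,saccular,impending
18,39,M,yes,yes,yes,yes,no,yes,9.8,0-0.5,0.35-0.5,1.2-1.6,24-30,high,fusiform,ruptured
19,80,M,yes,yes,yes,yes,no,yes,7.3,0.5-1,0.35-0.5,0.2-0.8,24-30,high,fusiform,ruptured
20,68,F,yes,yes,yes,yes,no,no,5.5,0-0.5,0.35-0.5,0.2-0.8,18-24,high,fusiform,ruptured
21,72,M,yes,yes,yes,yes,no,no,5.7,0-0.5,0.35-0.5,0.2-0.8,18-24,high,fusiform,ruptured
22,41,M,yes,yes,no,no,yes,yes,3.3,0-0.5,0.35-0.5,1.6-2,24-30,high,saccular,ruptured
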
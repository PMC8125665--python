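run,temperature_C,fa_wt_percent,time_h,A_CSF_ext,L_CSF_ext,SY_pct,GC_pct,XC_pct,LC_pct,XR_pct,DD_pct,FC_pct,EGC6_pct,EGC72_pct
1,80,60,0.25,35.95,37.11,68.7,56.17,17.93,21.16,54.5,39.06,1.3,4.1,11.6
2,80,70,0.5,38.75,39.97,64.7,63.7,14.2,18.9,66.2,48.6,2.3,6.0,22.3
3,80,80,1,41.27,42.56,51.6,74.2,10.9,13.6,79.4,70.7,3.9,4.8,29.2
4,80,90,1.5,43.29,44.63,43.4,77.9,6.3,6.7,89.9,88.3,4.7,3.2,36.0
5,90,60,0.5,37.33,38.52,64.7,52.4,17.4,19.4,58.4,47.5,1.7,10.4,35.5
6,90,70,0.25,38.74,40.00,79.1,60.4,13.4,13.9,60.9,54.6,2.1,10.7,42.1
7,90,80,1,41.96,43.28,49.6,64.6,13.2,10.7,75.9,77.9,3.6,8.0,48.6
8,90,90,1.5,43.97,45.35,45.9,71.6,9.9,5.9,90.8,89.2,5.2,3.9,42.3
9,99,60,1,38.64,39.86,63.0,69.4,11.5,17.3,70.2,58.3,1.93,8.6,40.8
10,99,70,1.5,41.15,42.45,46.0,74.5,9.1,10.8,82.8,81.5,2.0,6.1,44.6
11,99,80,0.25,41.19,42.54,46.1,73.7,10.9,11.8,79.4,79.8,2.23,6.2,44.4
12,99,90,0.5,32.28,44.90,54.2,81.5,6.5,7.3,85.5,85.5,2.39,4.9,49.8
13,105,60,1.5,39.46,40.70,63.0,65.9,10.2,18.0,76.2,51.6,1.7,12.2,44.8
14,105,70,1,41.16,42.46,53.6,69.7,10.8,13.1,78.7,70.5,2.4,7.9,43.8
15,105,80,0.5,42.30,43.66,46.7,83.0,7.9,7.6,84.8,87.1,2.42,5.9,54.1
16,105,90,0.25,43.21,44.64,46.7,81.4,7.0,6.7,86.6,88.7,2.28,5.4,53.4
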
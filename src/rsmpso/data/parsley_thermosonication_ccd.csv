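run_id,time_min,amplitude_pct,temperature_C,chlorophyll_mg_100mL,chlorophyll_sd,chlorophyll_rsm_pred,chlorophyll_mlr_pred,ascorbic_mg_100g,ascorbic_sd,ascorbic_rsm_pred,ascorbic_mlr_pred
1,6,70,45,7.76,0.04,7.69,7.07,128.16,2.83,126.93,126.59
2,8,80,50,7.41,0.10,7.53,6.76,114.86,1.62,116.17,113.52
3,6,90,45,5.86,0.08,5.90,6.52,113.32,1.60,112.41,119.65
4,10,90,45,5.72,0.54,5.71,6.34,105.30,1.15,104.14,107.19
5,6,70,55,6.84,0.48,6.88,7.18,123.12,2.81,124.51,119.85
6,10,70,55,5.46,0.41,5.45,7.00,98.28,1.67,99.42,107.39
7,6,90,55,7.52,0.53,7.47,6.63,124.50,2.12,123.32,112.91
8,8,80,50,7.58,0.11,7.53,6.76,116.47,1.65,116.17,113.52
9,8,80,50,7.56,0.13,7.53,6.76,115.92,1.36,116.17,113.52
10,10,90,55,6.25,0.09,6.36,6.45,100.53,1.42,101.98,100.45
11,4,80,50,6.70,0.47,6.71,6.94,120.60,1.34,121.70,125.98
12,12,80,50,5.18,0.37,5.09,6.58,89.69,0.59,88.34,101.06
13,8,60,50,6.12,0.06,6.09,7.31,108.78,2.81,107.59,120.46
14,8,100,50,5.26,0.37,5.21,6.21,94.68,1.82,95.62,106.58
15,8,80,40,7.35,0.16,7.33,6.65,132.30,2.08,133.30,120.26
16,8,80,60,7.22,0.51,7.16,6.87,129.96,2.57,128.72,106.78
17,8,80,50,7.44,0.63,7.53,6.76,116.43,0.37,116.17,113.52
18,8,80,50,7.65,0.65,7.53,6.76,117.70,1.78,116.17,113.52
19,8,80,50,7.65,0.18,7.53,6.76,115.92,1.15,116.17,113.52
20,10,70,45,7.10,0.03,7.18,6.88,113.52,1.22,114.92,114.13
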
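animal_id,gender,age_weeks,heart_rate,systolic_bp,hematocrit,body_weight_kg,ecv,cmyb_mean_um,cmyb_sd_um,status
1,M,10,136,109,0.30,26.0,0.272,10.87,1.55,analyzed
2,F,8,116,97,0.23,13.6,0.335,8.64,1.56,analyzed
3,F,9,133,91,0.21,20.0,0.325,9.06,1.48,analyzed
4,F,9,129,112,0.34,20.5,,,,died
5,M,10,120,106,0.31,26.0,0.292,8.96,1.38,analyzed
6,F,11,140,98,0.26,27.5,0.255,10.55,1.55,analyzed
7,M,10,119,101,0.35,23.0,0.252,9.33,1.24,analyzed
8,M,10,134,116,0.34,25.5,0.272,9.91,1.50,analyzed
9,M,9,109,113,0.37,25.0,0.202,10.23,1.70,analyzed
10,M,10,112,96,0.34,25.0,0.240,10.18,1.77,analyzed
11,M,10,110,117,0.36,25.0,0.219,10.75,1.15,analyzed
12,M,9,112,107,0.31,25.0,0.241,10.64,1.41,analyzed
13,F,12,126,92,0.29,30.0,0.232,9.28,1.37,analyzed
14,F,12,122,94,0.34,29.0,0.217,10.39,1.35,analyzed
15,F,10,134,105,0.34,23.0,0.190,11.48,2.07,analyzed
16,F,11,118,93,,25.0,,,,scan_failed
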
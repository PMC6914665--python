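participant_id,ingredient,min_abs_dose,max_abs_dose,consexpo,sccs_default,sccs_product_specific,raidar_ice_tier1,raidar_ice_empirical,sheds_p05,sheds_mean,sheds_p95,creme_p05,creme_mean,creme_p95
1,MP,12.13,69.69,21.46,12.04,5.61,105.00,17.37,0.03,0.85,3.12,0.01,0.78,3.85
2,MP,2.99,17.16,13.96,12.04,1.94,9.48,2.92,0.01,0.35,1.36,0.01,0.22,0.99
3,MP,0.63,3.62,2.30,12.04,2.24,1.64,6.55,0.38,2.57,7.42,0.90,3.96,9.56
4,MP,1.99,11.41,9.97,12.04,2.30,1.84,6.61,0.39,2.55,7.61,0.16,0.99,2.37
5,MP,4.26,24.50,0.86,12.04,0.89,8.45,2.72,0.01,0.30,1.20,0.22,2.69,9.17
6,MP,0.18,1.06,13.10,12.04,1.05,1.02,0.19,0.01,0.04,0.16,0.01,0.23,1.04
7,MP,0.80,4.61,12.86,12.04,1.05,9.45,2.91,0.01,0.35,1.36,0.01,0.23,1.04
8,MP,3.57,20.52,12.86,12.04,1.05,9.45,2.91,0.01,0.35,1.36,0.01,0.23,1.04
1,EP,2.29,16.68,8.53,12.04,0.95,6.05,2.69,0.01,0.32,1.27,0.01,0.22,1.05
2,EP,2.42,17.69,0.86,12.04,0.89,5.93,2.63,0.01,0.31,1.20,0.22,2.69,9.17
5,EP,0.99,7.23,0.86,12.04,0.89,5.93,2.63,0.01,0.31,1.20,0.22,2.69,9.17
1,PP,5.02,51.70,12.93,12.04,4.66,89.89,6.91,0.03,0.57,2.20,0.01,1.06,4.53
2,PP,0.04,0.38,5.43,12.04,0.99,0.82,0.09,0.00,0.04,0.15,0.01,0.38,1.59
3,PP,0.18,1.89,2.30,12.04,2.24,1.64,3.11,0.38,2.56,7.37,0.43,1.88,4.54
4,PP,0.52,5.34,2.30,12.04,2.24,1.64,3.11,0.38,2.56,7.37,0.43,1.88,4.54
5,PP,1.18,12.13,0.86,12.04,0.89,3.09,1.13,0.01,0.31,1.20,0.10,1.28,4.36
6,PP,0.01,0.12,5.43,12.04,0.99,0.82,0.09,0.01,0.04,0.15,0.01,0.38,1.59
7,PP,0.30,3.08,4.33,12.04,0.10,0.74,0.06,0.01,0.04,0.15,0.01,0.09,0.21
8,PP,0.02,0.19,4.33,12.04,0.10,0.74,0.06,0.01,0.04,0.15,0.01,0.09,0.21
1,TCS,35.09,64.98,2.30,22.72,2.40,1.64,4.91,0.38,2.57,7.41,0.67,2.97,7.17
2,TCS,21.98,40.70,2.30,22.72,2.40,1.64,4.91,0.38,2.57,7.41,0.67,2.97,7.17
5,TCS,17.23,31.91,14.80,22.72,1.82,2.54,3.06,0.04,0.39,1.24,0.02,0.22,0.94
6,TCS,6.42,11.90,2.30,22.72,2.40,1.64,4.91,0.38,2.57,7.41,0.67,2.97,7.17
7,TCS,10.66,19.74,2.30,22.72,2.40,1.64,4.91,0.38,2.57,7.41,0.67,2.97,7.17
8,TCS,10.14,18.78,2.30,22.72,2.40,1.64,4.91,0.38,2.57,7.41,0.67,2.97,7.17
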
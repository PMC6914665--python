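participant_id,body_weight_kg,ingredient,excreted_ug_kg_d,user
1,58,MP,12.13,1
1,58,EP,2.29,1
1,58,PP,5.02,1
1,58,TCS,35.09,1
2,92,MP,2.99,1
2,92,EP,2.42,1
2,92,PP,0.04,1
2,92,TCS,21.98,1
3,57,MP,0.63,1
3,57,EP,0.04,0
3,57,PP,0.18,1
3,57,TCS,0.01,0
4,85,MP,1.99,1
4,85,EP,0.18,0
4,85,PP,0.52,1
4,85,TCS,0.00,0
5,66,MP,4.26,1
5,66,EP,0.99,1
5,66,PP,1.18,1
5,66,TCS,17.23,1
6,95,MP,0.18,1
6,95,EP,0.05,0
6,95,PP,0.01,1
6,95,TCS,6.42,1
7,63,MP,0.80,1
7,63,EP,0.09,0
7,63,PP,0.30,1
7,63,TCS,10.66,1
8,78,MP,3.57,1
8,78,EP,0.50,0
8,78,PP,0.02,1
8,78,TCS,10.14,1
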
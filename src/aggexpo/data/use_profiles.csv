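participant_id,ingredient,product
1,MP,shampoo
1,MP,shower_gel
1,MP,day_cream
1,MP,body_lotion
1,EP,shampoo
1,EP,shower_gel
1,PP,shampoo
1,PP,shower_gel
1,TCS,toothpaste
2,MP,shampoo
2,MP,shower_gel
2,MP,day_cream
2,MP,deodorant
2,EP,shower_gel
2,PP,shampoo
2,PP,shower_gel
2,TCS,toothpaste
3,MP,toothpaste
3,PP,toothpaste
4,MP,toothpaste
4,MP,shower_gel
4,PP,toothpaste
5,MP,day_cream
5,EP,day_cream
5,PP,day_cream
5,TCS,deodorant
5,TCS,shower_gel
6,MP,shampoo
6,MP,shower_gel
6,MP,day_cream
6,PP,shampoo
6,PP,shower_gel
6,TCS,toothpaste
7,MP,shampoo
7,MP,shower_gel
7,MP,shaving_cream
7,PP,shower_gel
7,TCS,toothpaste
8,MP,shampoo
8,MP,shower_gel
8,MP,shaving_cream
8,PP,shower_gel
8,TCS,toothpaste
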
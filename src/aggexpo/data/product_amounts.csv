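source,body_lotion,day_cream,deodorant,shampoo,shaving_cream,shower_gel,toothpaste
consexpo,8,0.8,5.2,20,2,8.7,
sccs,7.82,1.54,1.43,10.46,1.54,18.67,2.75
sheds,8,5,2,12,2,12,6
creme,3.63,1.33,2.36,7.59,1.33,8.86,1.55
raidar,7.82,1.54,1.43,10.46,1.54,18.67,2.75
observed,8.65,1.37,6.97,5.75,1.71,6.87,2.35
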
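model,vs_min_abs_dose,vs_max_abs_dose
consexpo,0.018,0.054
sccs_default,0.701,0.467
sccs_product_specific,0.602,0.521
raidar_ice_tier1,0.378,0.555
raidar_ice_empirical,0.649,0.609
sheds_p05,0.438,0.353
sheds_mean,0.648,0.512
sheds_p95,0.554,0.441
creme_p05,0.355,0.224
creme_mean,0.41,0.312
creme_p95,0.320,0.290
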
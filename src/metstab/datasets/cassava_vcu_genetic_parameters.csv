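parameter,FRY,DMC
var_g,20.16,3.46
var_ge,17.87,0.68
var_e,6.54,0.42
var_p,44.57,4.56
h2,0.45,0.75
cv_g,17.18,5.14
cv_p,25.53,5.84
cv_r,9.78,1.80
cv_ratio,1.75,2.85
p_minus_g,8.35,0.70
ga,6.38,3.13
gam,24.40,8.64
grand_mean,26.14,36.22
selective_accuracy,0.96,0.99
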
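trait,source,df,ss
FRY,genotypes,11,8645.52
FRY,environments,11,8780.89
FRY,blocks_within_env,24,371.10
FRY,gxe,121,7279.50
FRY,pc1,21,2390.07
FRY,pc2,19,1506.66
FRY,residual,264,1726.49
DMC,genotypes,11,1400.56
DMC,environments,11,479.66
DMC,blocks_within_env,24,24.45
DMC,gxe,121,301.72
DMC,pc1,21,115.66
DMC,pc2,19,63.00
DMC,residual,264,112.63
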
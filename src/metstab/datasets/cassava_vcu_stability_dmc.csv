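genotype,mean,sk_letter,dp,dp_rank,waasb,waasb_rank,asv,asv_rank,gge,gge_rank,wi,wi_rank,pi,pi_rank,si1,si1_rank,si6,si6_rank,hmgv,hmgv_rank,s2di,s2di_rank,rmse,rmse_rank,r2,r2_rank,bi,bi_rank,di,di_rank,lig,lig_rank,lif,lif_rank,lid,lid_rank,s2x,s2x_rank
BR11-34-45,36.69,c,1.77,11,0.59,11,1.49,7,-1.08,7,14.10,3,3.84,7,0.02,2,2.56,5,36.6,7,0.63,7,0.80,7,0.77,4,0.42,1,0.78,7,96.97,7,99.11,5,96.58,6,3.45,9
Cigana Preta,36.80,c,1.77,12,0.56,9,1.96,11,-1.84,12,31.60,10,3.83,6,0.06,7,2.79,6,36.7,6,0.66,9,0.82,9,0.76,5,0.41,2,0.81,9,97.12,6,98.31,6,95.38,8,5.27,11
BR11-34-64,34.14,d,1.49,8,0.25,3,0.52,3,-0.98,5,30.35,8,13.93,10,0.05,5,4.35,9,34.1,10,0.31,4,0.61,4,0.81,2,0.22,3,0.46,4,90.98,9,91.76,9,89.81,10,1.45,4
BR12-107-002,37.46,b,1.56,10,0.49,7,1.54,8,-1.29,8,15.71,4,2.25,3,0.03,4,1.84,4,37.4,4,0.65,8,0.81,8,0.70,7,0.19,4,0.79,8,99.45,4,101.42,2,97.31,5,3.36,8
Corrente,37.90,b,1.43,7,0.36,5,1.17,6,-0.72,4,10.01,2,1.34,2,0.06,7,1.16,2,37.9,2,0.45,5,0.70,5,0.73,6,0.11,5,0.60,5,101.28,2,100.83,3,102.24,2,2.27,5
BRS Novo Horizonte,39.33,a,1.25,6,0.18,1,0.27,1,0.67,3,25.26,7,0.01,1,0.09,11,0.28,1,39.3,1,0.07,1,0.42,1,0.87,1,0.06,6,0.21,1,106.57,1,107.32,1,105.78,1,0.18,1
BR11-34-41,33.45,e,1.50,9,0.57,10,1.78,10,0.66,2,22.20,6,18.10,12,0.11,12,4.92,12,33.4,12,0.91,11,0.93,11,0.57,9,0.03,7,1.05,11,87.85,12,88.27,11,86.83,12,1.45,3
BR11-34-69,33.68,e,1.21,3,0.23,2,0.32,2,-1.06,6,41.27,11,16.55,11,0.02,2,4.89,11,33.6,11,0.19,2,0.52,2,0.79,3,-0.02,8,0.33,2,90.42,10,91.28,10,89.56,11,1.18,2
BRS Formosa,36.23,c,1.23,5,0.41,6,1.03,4,0.65,1,6.59,1,5.41,8,0.08,9,3.05,7,36.2,8,0.56,6,0.76,6,0.57,10,-0.15,9,0.71,6,96.26,8,96.99,8,96.35,7,4.36,10
BR11-24-156,37.13,b,1.10,2,0.35,4,1.11,5,1.39,9,30.95,9,2.78,5,0.00,1,1.75,3,37.1,5,0.28,3,0.59,3,0.67,8,-0.17,10,0.43,3,99.47,3,99.36,4,99.33,3,2.55,6
BRS Mulatinha,37.46,b,1.09,1,0.55,8,1.60,9,1.79,10,18.52,5,2.33,4,0.06,7,3.21,8,37.4,3,0.86,10,0.91,10,0.22,11,-0.53,11,1.01,10,98.27,5,97.98,7,98.85,4,6.45,12
IAC-90,34.35,d,1.22,4,0.77,12,2.66,12,1.81,11,55.14,12,13.65,9,0.08,9,4.80,10,34.3,9,1.25,12,1.08,12,0.14,12,-0.57,12,1.40,12,89.08,11,87.47,12,92.70,9,3.09,7
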
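genotype,mean,sk_letter,dp,dp_rank,waasb,waasb_rank,asv,asv_rank,gge,gge_rank,wi,wi_rank,pi,pi_rank,si1,si1_rank,si6,si6_rank,hmgv,hmgv_rank,s2di,s2di_rank,rmse,rmse_rank,r2,r2_rank,bi,bi_rank,di,di_rank,lig,lig_rank,lif,lif_rank,lid,lid_rank,s2x,s2x_rank
BR11-24-156,24.64,g,5.41,2,0.50,1,0.89,2,0.32,2,64.67,1,76.62,7,0.06,8,4.12,8,23.4,9,4.27,1,2.31,1,0.80,1,0.03,6,6.45,1,86.9,8,89.0,7,85.4,9,6.0,5
Cigana Preta,22.14,h,7.10,10,1.17,11,1.57,4,-0.29,1,235.16,10,111.58,10,0.11,12,6.97,11,20.2,11,20.76,10,4.37,10,0.59,7,0.15,4,22.94,10,70.9,11,78.9,9,65.3,11,8.11,9
Corrente,24.71,g,5.51,4,1.08,10,2.01,6,4.46,7,123.01,3,79.97,9,0.06,8,4.28,9,23.6,8,10.01,3,3.18,3,0.63,5,-0.07,9,12.19,3,85.9,9,84.9,8,86.0,8,5.48,3
IAC-90,16.03,i,6.37,7,0.73,2,2.61,7,-5.76,9,200.80,6,224.17,12,0.03,4,7.27,12,14.0,12,17.90,8,4.09,8,0.55,9,0.00,7,20.08,8,48.0,12,58.2,12,42.7,12,4.0,2
BR11-34-41,33.57,a,7.85,12,1.04,8,2.69,8,-2.83,4,205.39,7,11.58,1,0.06,8,1.12,1,32.1,1,12.98,6,3.55,6,0.78,2,0.47,1,15.16,6,118.0,1,124.0,1,114.0,1,1.48,1
BR11-34-45,28.66,d,7.63,11,0.75,3,3.65,11,-9.35,11,213.30,8,38.21,4,0.03,4,3.77,6,27.2,4,15.72,7,3.86,7,0.72,4,0.38,2,17.9,7,99.0,4,99.7,4,98.0,5,7.75,7
BR11-34-64,26.53,f,6.43,8,1.07,9,1.97,5,-5.10,8,115.14,2,60.88,6,0.03,4,3.08,3,25.1,7,8.39,2,2.96,2,0.77,3,0.20,3,10.57,2,91.9,6,101.0,3,86.7,7,6.39,6
BR11-34-69,31.49,b,6.98,9,1.55,12,3.03,9,-3.80,6,227.14,9,19.36,2,0.08,10,2.69,2,30.2,2,20.11,9,4.30,9,0.58,8,0.13,5,22.29,9,109.0,2,105.0,2,110.0,2,8.45,10
BR12-107-002,22.50,h,5.13,1,0.86,6,0.76,1,-2.85,5,161.39,5,113.67,11,0.09,11,5.18,10,21.6,10,12.57,4,3.50,4,0.49,10,-0.24,10,14.75,4,76.7,10,73.3,11,78.5,10,5.73,4
BRS Formosa,29.67,c,5.89,5,0.80,4,3.25,10,6.44,10,280.66,11,31.90,3,0.05,6,3.33,4,28.6,3,23.79,11,4.65,11,0.32,11,-0.29,11,25.97,11,101.0,3,99.1,5,107.0,3,8.09,8
BRS Mulatinha,26.33,f,5.49,3,0.81,5,5.72,12,17.03,12,450.70,12,77.02,8,0.02,1,3.69,5,25.4,6,29.35,12,5.12,12,0.05,12,-0.75,12,31.53,12,88.6,7,75.5,10,99.6,4,9.2,12
BRS Novo Horizonte,27.40,e,5.93,6,1.04,7,1.27,3,1.73,3,149.16,4,45.98,5,0.03,4,3.93,7,26.3,5,12.73,5,3.52,5,0.61,6,-0.01,8,14.91,5,95.1,5,92.7,6,96.4,6,8.82,11
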
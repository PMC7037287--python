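area,distance_km,variety,compartment,depth_cm,element,value,sd,n,unit,censored
Baia Mare,,n/a,soil,0-20,Cu,2510.52,164.99,3,mg/kg DW,0
Baia Mare,,n/a,soil,0-20,Zn,1637.98,141.78,3,mg/kg DW,0
Baia Mare,,n/a,soil,0-20,Pb,3074.29,201.65,3,mg/kg DW,0
Baia Mare,,n/a,soil,0-20,Cd,14.13,1.36,3,mg/kg DW,0
Baia Mare,,n/a,soil,0-20,Ni,28.6,3.51,3,mg/kg DW,0
Baia Mare,,n/a,soil,0-20,Co,29.57,1.65,3,mg/kg DW,0
Baia Mare,,n/a,soil,0-20,As,4.13,0.52,3,mg/kg DW,0
Baia Mare,,n/a,soil,0-20,Cr,2.25,0.79,3,mg/kg DW,0
Baia Mare,,n/a,soil,0-20,Hg,0.058,0.025,3,mg/kg DW,0
Baia Mare,,n/a,soil,20-40,Cu,3317.02,156.3,3,mg/kg DW,0
Baia Mare,,n/a,soil,20-40,Zn,1317.48,68.87,3,mg/kg DW,0
Baia Mare,,n/a,soil,20-40,Pb,3419.25,196.78,3,mg/kg DW,0
Baia Mare,,n/a,soil,20-40,Cd,13.79,0.74,3,mg/kg DW,0
Baia Mare,,n/a,soil,20-40,Ni,27.59,1.28,3,mg/kg DW,0
Baia Mare,,n/a,soil,20-40,Co,19.91,1.76,3,mg/kg DW,0
Baia Mare,,n/a,soil,20-40,As,3.16,0.99,3,mg/kg DW,0
Baia Mare,,n/a,soil,20-40,Cr,1.49,0.6,3,mg/kg DW,0
Baia Mare,,n/a,soil,20-40,Hg,0.053,0.025,3,mg/kg DW,0
Baia Mare,,n/a,soil,40-60,Cu,3146.25,124.62,3,mg/kg DW,0
Baia Mare,,n/a,soil,40-60,Zn,2266.07,93.58,3,mg/kg DW,0
Baia Mare,,n/a,soil,40-60,Pb,3118.06,149.57,3,mg/kg DW,0
Baia Mare,,n/a,soil,40-60,Cd,15.66,0.71,3,mg/kg DW,0
Baia Mare,,n/a,soil,40-60,Ni,25.43,2.7,3,mg/kg DW,0
Baia Mare,,n/a,soil,40-60,Co,20.21,1.09,3,mg/kg DW,0
Baia Mare,,n/a,soil,40-60,As,4.05,0.45,3,mg/kg DW,0
Baia Mare,,n/a,soil,40-60,Cr,2.72,0.65,3,mg/kg DW,0
Baia Mare,,n/a,soil,40-60,Hg,0.053,0.012,3,mg/kg DW,0
Baia Mare,,n/a,soil,60-80,Cu,3687.25,81.82,3,mg/kg DW,0
Baia Mare,,n/a,soil,60-80,Zn,2734.93,147.45,3,mg/kg DW,0
Baia Mare,,n/a,soil,60-80,Pb,3544.34,166.99,3,mg/kg DW,0
Baia Mare,,n/a,soil,60-80,Cd,19.78,1.41,3,mg/kg DW,0
Baia Mare,,n/a,soil,60-80,Ni,19.52,0.79,3,mg/kg DW,0
Baia Mare,,n/a,soil,60-80,Co,21.98,1.69,3,mg/kg DW,0
Baia Mare,,n/a,soil,60-80,As,2.49,0.57,3,mg/kg DW,0
Baia Mare,,n/a,soil,60-80,Cr,2.15,0.01,3,mg/kg DW,0
Baia Mare,,n/a,soil,60-80,Hg,0.042,0.024,3,mg/kg DW,0
Baia Sprie,,n/a,soil,0-20,Cu,4073.87,182.03,3,mg/kg DW,0
Baia Sprie,,n/a,soil,0-20,Zn,3134.45,137.89,3,mg/kg DW,0
Baia Sprie,,n/a,soil,0-20,Pb,3677.95,148.11,3,mg/kg DW,0
Baia Sprie,,n/a,soil,0-20,Cd,23.25,1.25,3,mg/kg DW,0
Baia Sprie,,n/a,soil,0-20,Ni,18.0,1.38,3,mg/kg DW,0
Baia Sprie,,n/a,soil,0-20,Co,8.41,0.95,3,mg/kg DW,0
Baia Sprie,,n/a,soil,0-20,As,5.13,1.22,3,mg/kg DW,0
Baia Sprie,,n/a,soil,0-20,Cr,2.58,1.25,3,mg/kg DW,0
Baia Sprie,,n/a,soil,0-20,Hg,0.068,0.029,3,mg/kg DW,0
Baia Sprie,,n/a,soil,20-40,Cu,3998.09,9.69,3,mg/kg DW,0
Baia Sprie,,n/a,soil,20-40,Zn,2934.62,243.58,3,mg/kg DW,0
Baia Sprie,,n/a,soil,20-40,Pb,4262.23,156.0,3,mg/kg DW,0
Baia Sprie,,n/a,soil,20-40,Cd,19.52,1.01,3,mg/kg DW,0
Baia Sprie,,n/a,soil,20-40,Ni,16.16,1.91,3,mg/kg DW,0
Baia Sprie,,n/a,soil,20-40,Co,11.39,1.03,3,mg/kg DW,0
Baia Sprie,,n/a,soil,20-40,As,4.49,2.49,3,mg/kg DW,0
Baia Sprie,,n/a,soil,20-40,Cr,2.35,0.34,3,mg/kg DW,0
Baia Sprie,,n/a,soil,20-40,Hg,0.07,0.017,3,mg/kg DW,0
Baia Sprie,,n/a,soil,40-60,Cu,3855.49,58.38,3,mg/kg DW,0
Baia Sprie,,n/a,soil,40-60,Zn,3323.19,157.94,3,mg/kg DW,0
Baia Sprie,,n/a,soil,40-60,Pb,4181.79,144.3,3,mg/kg DW,0
Baia Sprie,,n/a,soil,40-60,Cd,32.53,0.99,3,mg/kg DW,0
Baia Sprie,,n/a,soil,40-60,Ni,17.22,2.33,3,mg/kg DW,0
Baia Sprie,,n/a,soil,40-60,Co,7.18,0.99,3,mg/kg DW,0
Baia Sprie,,n/a,soil,40-60,As,4.72,1.01,3,mg/kg DW,0
Baia Sprie,,n/a,soil,40-60,Cr,2.39,1.15,3,mg/kg DW,0
Baia Sprie,,n/a,soil,40-60,Hg,0.067,0.012,3,mg/kg DW,0
Baia Sprie,,n/a,soil,60-80,Cu,4155.95,79.3,3,mg/kg DW,0
Baia Sprie,,n/a,soil,60-80,Zn,3483.25,94.11,3,mg/kg DW,0
Baia Sprie,,n/a,soil,60-80,Pb,4127.23,193.63,3,mg/kg DW,0
Baia Sprie,,n/a,soil,60-80,Cd,32.06,1.4,3,mg/kg DW,0
Baia Sprie,,n/a,soil,60-80,Ni,18.23,0.4,3,mg/kg DW,0
Baia Sprie,,n/a,soil,60-80,Co,6.01,1.33,3,mg/kg DW,0
Baia Sprie,,n/a,soil,60-80,As,3.49,1.52,3,mg/kg DW,0
Baia Sprie,,n/a,soil,60-80,Cr,1.94,0.37,3,mg/kg DW,0
Baia Sprie,,n/a,soil,60-80,Hg,0.052,0.008,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,0-20,Cu,621.79,64.64,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,0-20,Zn,76.86,7.71,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,0-20,Pb,12.62,2.76,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,0-20,Cd,0.27,0.04,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,0-20,Ni,7.82,1.81,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,0-20,Co,5.08,1.77,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,0-20,As,2.04,0.03,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,0-20,Cr,0.96,0.41,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,0-20,Hg,0.048,0.032,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,20-40,Cu,791.71,50.85,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,20-40,Zn,68.18,3.09,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,20-40,Pb,6.62,0.45,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,20-40,Cd,0.22,0.15,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,20-40,Ni,12.14,1.53,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,20-40,Co,8.8,1.05,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,20-40,As,2.16,0.03,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,20-40,Cr,0.68,0.53,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,20-40,Hg,0.06,0.017,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,40-60,Cu,842.88,68.11,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,40-60,Zn,45.36,10.19,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,40-60,Pb,6.95,1.68,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,40-60,Cd,0.15,0.06,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,40-60,Ni,5.89,1.17,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,40-60,Co,10.08,1.24,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,40-60,As,2.05,0.57,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,40-60,Cr,1.39,0.21,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,40-60,Hg,0.57,0.006,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,60-80,Cu,793.69,8.64,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,60-80,Zn,45.56,9.79,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,60-80,Pb,7.76,1.83,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,60-80,Cd,0.12,0.1,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,60-80,Ni,6.97,0.49,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,60-80,Co,8.43,0.93,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,60-80,As,1.15,0.01,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,60-80,Cr,1.45,0.61,3,mg/kg DW,0
Simleul Silvaniei,,n/a,soil,60-80,Hg,0.034,0.01,3,mg/kg DW,0
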
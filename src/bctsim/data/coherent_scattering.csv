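# Coherent (Rayleigh) mass scattering coefficients mu_coh/rho (cm^2/g).
# APPROXIMATE values: H,C,N,O follow XCOM-style magnitudes; Na,P,S,Cl,K are
# scaled from O by (Z/8)^2.5 * (16/A). Used only to partition the Monte Carlo
# interaction channels (coherent events scatter without energy deposition);
# the photoelectric channel is taken as the residual of the exact packaged
# total, so these values never affect total attenuation lengths.
element,energy_keV,mu_coh_over_rho_cm2_g
H,8,0.0060
H,10,0.0046
H,15,0.0025
H,20,0.0016
H,30,0.0008
H,40,0.0005
H,50,0.0003
H,60,0.0002
H,80,0.0001
C,8,0.180
C,10,0.125
C,15,0.068
C,20,0.042
C,30,0.020
C,40,0.0115
C,50,0.0077
C,60,0.0055
C,80,0.0032
N,8,0.220
N,10,0.155
N,15,0.085
N,20,0.053
N,30,0.025
N,40,0.0147
N,50,0.0098
N,60,0.0070
N,80,0.0041
O,8,0.270
O,10,0.190
O,15,0.104
O,20,0.065
O,30,0.031
O,40,0.018
O,50,0.012
O,60,0.0085
O,80,0.0050
Na,8,0.416
Na,10,0.293
Na,15,0.160
Na,20,0.100
Na,30,0.0477
Na,40,0.0277
Na,50,0.0185
Na,60,0.0131
Na,80,0.0077
P,8,0.672
P,10,0.473
P,15,0.259
P,20,0.162
P,30,0.0772
P,40,0.0448
P,50,0.0299
P,60,0.0212
P,80,0.0125
S,8,0.764
S,10,0.538
S,15,0.294
S,20,0.184
S,30,0.0877
S,40,0.0509
S,50,0.0340
S,60,0.0241
S,80,0.0142
Cl,8,0.805
Cl,10,0.566
Cl,15,0.310
Cl,20,0.194
Cl,30,0.0924
Cl,40,0.0536
Cl,50,0.0358
Cl,60,0.0253
Cl,80,0.0149
K,8,0.964
K,10,0.678
K,15,0.371
K,20,0.232
K,30,0.1107
K,40,0.0643
K,50,0.0428
K,60,0.0303
K,80,0.0179
air,8,0.239
air,10,0.169
air,15,0.0924
air,20,0.0576
air,30,0.0273
air,40,0.0160
air,50,0.0107
air,60,0.0076
air,80,0.0045
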
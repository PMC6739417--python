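# Total mass attenuation coefficients mu/rho (cm^2/g), including coherent scattering.
# Transcribed from the NIST standard reference tables of X-ray mass attenuation
# coefficients (Hubbell & Seltzer), elemental media plus dry air (near sea level),
# on the published energy grid. Values are interpolated log-log between grid points;
# no K-edges fall inside 8-80 keV for these media. Trace elements (Na,P,S,Cl,K)
# contribute <1% of tissue mass and are transcribed at reduced precision.
element,energy_keV,mu_over_rho_cm2_g
H,8,0.3914
H,10,0.3854
H,15,0.3764
H,20,0.3695
H,30,0.3570
H,40,0.3458
H,50,0.3355
H,60,0.3260
H,80,0.3091
C,8,4.576
C,10,2.373
C,15,0.8071
C,20,0.4420
C,30,0.2562
C,40,0.2076
C,50,0.1871
C,60,0.1753
C,80,0.1610
N,8,7.562
N,10,3.879
N,15,1.236
N,20,0.6178
N,30,0.3066
N,40,0.2288
N,50,0.1980
N,60,0.1817
N,80,0.1639
O,8,11.63
O,10,5.952
O,15,1.836
O,20,0.8651
O,30,0.3779
O,40,0.2585
O,50,0.2132
O,60,0.1907
O,80,0.1678
Na,8,30.98
Na,10,15.79
Na,15,4.907
Na,20,2.126
Na,30,0.7214
Na,40,0.3928
Na,50,0.2756
Na,60,0.2238
Na,80,0.1873
P,8,77.55
P,10,40.27
P,15,12.45
P,20,5.358
P,30,1.700
P,40,0.8096
P,50,0.4916
P,60,0.3494
P,80,0.2324
S,8,96.50
S,10,50.12
S,15,15.50
S,20,6.708
S,30,2.113
S,40,0.9872
S,50,0.5849
S,60,0.4053
S,80,0.2585
Cl,8,109.7
Cl,10,57.25
Cl,15,17.84
Cl,20,7.739
Cl,30,2.424
Cl,40,1.117
Cl,50,0.6483
Cl,60,0.4395
Cl,80,0.2696
K,8,151.8
K,10,79.10
K,15,25.03
K,20,10.92
K,30,3.413
K,40,1.541
K,50,0.8679
K,60,0.5678
K,80,0.3251
air,8,9.921
air,10,5.120
air,15,1.614
air,20,0.7779
air,30,0.3538
air,40,0.2485
air,50,0.2080
air,60,0.1875
air,80,0.1662
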
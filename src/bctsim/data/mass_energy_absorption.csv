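# Mass energy-absorption coefficients mu_en/rho (cm^2/g).
# Transcribed from the NIST standard reference tables (Hubbell & Seltzer),
# elemental media plus dry air (near sea level), on the published energy grid.
# Log-log interpolated between grid points. Trace elements at reduced precision.
element,energy_keV,mu_en_over_rho_cm2_g
H,8,0.009211
H,10,0.009849
H,15,0.01102
H,20,0.01355
H,30,0.01863
H,40,0.02315
H,50,0.02709
H,60,0.03053
H,80,0.03620
C,8,4.242
C,10,2.078
C,15,0.5627
C,20,0.2238
C,30,0.06614
C,40,0.03343
C,50,0.02397
C,60,0.02098
C,80,0.02037
N,8,7.103
N,10,3.545
N,15,0.9557
N,20,0.3754
N,30,0.1058
N,40,0.04792
N,50,0.03088
N,60,0.02512
N,80,0.02245
O,8,11.01
O,10,5.565
O,15,1.545
O,20,0.6179
O,30,0.1729
O,40,0.07469
O,50,0.04414
O,60,0.03335
O,80,0.02735
Na,8,29.66
Na,10,15.00
Na,15,4.577
Na,20,1.919
Na,30,0.5967
Na,40,0.2625
Na,50,0.1454
Na,60,0.09737
Na,80,0.06129
P,8,75.00
P,10,38.86
P,15,11.70
P,20,4.982
P,30,1.521
P,40,0.6567
P,50,0.3494
P,60,0.2166
P,80,0.1187
S,8,93.00
S,10,48.57
S,15,14.63
S,20,6.240
S,30,1.916
S,40,0.8271
S,50,0.4390
S,60,0.2702
S,80,0.1449
Cl,8,106.0
Cl,10,55.37
Cl,15,16.83
Cl,20,7.227
Cl,30,2.233
Cl,40,0.9650
Cl,50,0.5109
Cl,60,0.3140
Cl,80,0.1665
K,8,147.0
K,10,76.30
K,15,23.63
K,20,10.21
K,30,3.190
K,40,1.385
K,50,0.7327
K,60,0.4487
K,80,0.2347
air,8,9.446
air,10,4.742
air,15,1.334
air,20,0.5389
air,30,0.1537
air,40,0.06833
air,50,0.04098
air,60,0.03041
air,80,0.02407
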
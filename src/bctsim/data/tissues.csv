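# Breast tissue elemental compositions (mass fractions) and densities.
# Adipose and glandular compositions after Hammerstein et al. (1979), in the
# 5-element transcription widely used in breast dosimetry Monte Carlo work
# (the sub-percent ash is assigned to phosphorus); densities after
# Hammerstein et al. / Boone & Chavez: adipose 0.93 g/cm^3, glandular 1.04 g/cm^3.
# Mass fractions of each tissue sum to 1 exactly.
tissue,element,mass_fraction,density_g_cm3
adipose,H,0.112,0.93
adipose,C,0.619,0.93
adipose,N,0.017,0.93
adipose,O,0.251,0.93
adipose,P,0.001,0.93
glandular,H,0.102,1.04
glandular,C,0.184,1.04
glandular,N,0.032,1.04
glandular,O,0.677,1.04
glandular,P,0.005,1.04
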
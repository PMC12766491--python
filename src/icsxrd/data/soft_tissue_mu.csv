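# Mass attenuation coefficient of soft tissue (ICRU-44 composition),
# values in cm^2/g on a keV grid, after the NIST XCOM/Hubbell-Seltzer
# reference tabulation. Convert to linear coefficients with the tissue
# density (default 1.06 g/cm^3).
# energy_keV,mu_over_rho_cm2_g
5,41.2
8,10.63
10,5.367
15,1.688
20,0.8205
30,0.3783
40,0.2699
50,0.2264
60,0.2048
80,0.1823
100,0.1693
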
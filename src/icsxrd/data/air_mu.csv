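# Mass attenuation coefficient of dry air (near sea level), cm^2/g,
# after the NIST reference tabulation. Density 1.205e-3 g/cm^3 at 20 C.
# energy_keV,mu_over_rho_cm2_g
5,40.27
8,9.921
10,5.120
15,1.614
20,0.7779
30,0.3538
40,0.2485
50,0.2080
60,0.1875
80,0.1662
100,0.1541
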
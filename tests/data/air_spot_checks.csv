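# Published dry-air mass coefficients, cm^2/g.
# mu_over_rho is the XCOM total attenuation WITHOUT coherent scattering,
# matching the channel model of the bundled tables; muen_over_rho is the
# Hubbell & Seltzer mass energy-absorption coefficient.
energy_MeV,mu_over_rho,muen_over_rho
0.1,0.1492,0.02325
1.0,0.0636,0.02789
10.0,0.0204,0.01450
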
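# Linear X-ray attenuation of crystalline silicon (density 2.33 g/cm^3).
# mu_per_mm = (mu/rho)[cm^2/g] * 2.33 [g/cm^3] * 0.1 [cm/mm].
# (mu/rho) values are the NIST (Hubbell & Seltzer / XCOM) total mass
# attenuation coefficients WITH coherent scattering for elemental Si.
# Intended interpolation: linear in log(energy) vs log(mu).
energy_keV,mu_per_mm
4.0,105.5257
5.0,57.0850
6.0,34.2510
8.0,15.0704
10.0,7.8964
15.0,2.4092
20.0,1.0401
30.0,0.3346
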
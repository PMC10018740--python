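# Nuclear g-factors (dimensionless, mu = g_X * I * mu_N) and spins for the
# isotopes the hyperfine module tabulates.  Values from the standard
# magnetic-moment compilations (Stone, Table of Nuclear Magnetic Dipole and
# Electric Quadrupole Moments, IAEA).
isotope,element,spin,g_factor
1H,H,0.5,5.58569468
2H,H,1.0,0.8574382
13C,C,0.5,1.4048236
14N,N,1.0,0.40376100
15N,N,0.5,-0.56637768
17O,O,2.5,-0.757516
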
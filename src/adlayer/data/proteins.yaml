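# Neutron scattering constants for the COE-3 IgG1 antibody and its
# Fab/Fc fragments.  mw in g/mol, volume in A^3, sld_by_contrast maps
# solvent SLD (A^-2) to protein SLD (A^-2): entries at pure H2O
# (-0.56e-6), CM4 (4.0e-6) and pure D2O (6.35e-6).  The protein SLD
# varies with contrast through labile-hydrogen exchange.
COE3:
  mw: 144827
  volume: 171740
  sld_by_contrast:
    -0.56e-6: 1.94e-6
    4.0e-6: 2.88e-6
    6.35e-6: 3.36e-6
Fc:
  mw: 49970
  volume: 59664
  sld_by_contrast:
    -0.56e-6: 1.906e-6
    4.0e-6: 2.79e-6
    6.35e-6: 3.25e-6
Fab:
  mw: 47429
  volume: 56038
  sld_by_contrast:
    -0.56e-6: 1.95e-6
    4.0e-6: 2.91e-6
    6.35e-6: 3.41e-6
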
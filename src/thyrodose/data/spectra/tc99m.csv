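# nuclide: Tc-99m
# half_life_hours: 6.0067
# ENSDF-derived fixture for the isomeric transition of Tc-99m: the 140.5 keV
# gamma, Tc K X-rays, conversion electrons and Auger groups; yields per decay.
# Sub-0.1% lines retained in-file, dropped on load.
kind,energy_MeV,yield,daughter_Z
photon,0.140511,0.885,0
photon,0.018367,0.0405,0
photon,0.018251,0.0213,0
photon,0.020619,0.0122,0
photon,0.142630,0.00023,0
conversion,0.119467,0.0879,0
conversion,0.137490,0.0107,0
conversion,0.140110,0.0022,0
conversion,0.121600,0.0047,0
auger,0.015400,0.0202,0
auger,0.002160,0.7460,0
conversion,0.002130,0.00089,0
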
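# nuclide: I-131
# half_life_hours: 192.48
# ENSDF-derived fixture: photon lines, beta branches (endpoint energies,
# daughter Z = 54), conversion and Auger electrons; yields per decay.
# Lines at or below 0.1% yield are retained in the file so the loader's
# yield cut is exercised; they are dropped on load.
kind,energy_MeV,yield,daughter_Z
photon,0.080185,0.0262,0
photon,0.2843,0.0612,0
photon,0.364489,0.815,0
photon,0.636989,0.0716,0
photon,0.722911,0.0177,0
photon,0.325789,0.00274,0
photon,0.642719,0.00217,0
photon,0.029458,0.0206,0
photon,0.029779,0.0383,0
photon,0.033624,0.0105,0
photon,0.302400,0.00055,0
photon,0.085900,0.00090,0
beta_minus,0.606300,0.896,54
beta_minus,0.333800,0.0723,54
beta_minus,0.247900,0.0208,54
beta_minus,0.806900,0.0040,54
beta_minus,0.629700,0.00048,54
conversion,0.329900,0.0155,0
conversion,0.358900,0.00246,0
conversion,0.045600,0.0354,0
conversion,0.074600,0.00462,0
conversion,0.079700,0.00105,0
conversion,0.249700,0.00252,0
conversion,0.602200,0.00076,0
auger,0.003680,0.0550,0
auger,0.024600,0.0051,0
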
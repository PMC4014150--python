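# nuclide: I-123
# half_life_hours: 13.27
# ENSDF-derived fixture for the electron-capture decay of I-123: gamma lines,
# Te K/L X-rays, conversion electrons and Auger groups; yields per decay.
# Sub-0.1% lines retained in-file, dropped on load.
kind,energy_MeV,yield,daughter_Z
photon,0.158970,0.833,0
photon,0.528960,0.0139,0
photon,0.440020,0.00428,0
photon,0.505330,0.00316,0
photon,0.538540,0.00382,0
photon,0.628290,0.00183,0
photon,0.027472,0.246,0
photon,0.027202,0.132,0
photon,0.030990,0.0707,0
photon,0.003900,0.0950,0
photon,0.346350,0.00126,0
photon,0.735780,0.00062,0
conversion,0.127200,0.1360,0
conversion,0.154600,0.0178,0
conversion,0.158400,0.00441,0
conversion,0.497100,0.00300,0
auger,0.018500,0.0600,0
auger,0.003100,1.0000,0
conversion,0.501400,0.00041,0
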
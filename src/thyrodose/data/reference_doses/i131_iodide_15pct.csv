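# Published organ doses (mGy/MBq) for 131I sodium iodide at 15% thyroid
# uptake in the adult male/female reference voxel phantoms; inputs for the
# effective-dose worked example. The female esophagus row is typographically
# garbled in the source table; only its Total value (1.20) is carried.
organ,male_mGy_per_MBq,female_mGy_per_MBq
Active red marrow,1.09E-01,1.27E-01
Colon,4.85E-02,4.92E-02
Lungs,1.67E-01,1.84E-01
Stomach wall,5.56E-01,5.92E-01
Breasts,4.41E-02,8.15E-02
Testes/Ovaries,2.33E-02,6.01E-02
Urinary bladder wall,1.40E-01,1.57E-01
Esophagus,1.07,1.20
Liver,5.33E-02,5.98E-02
Thyroid,207.19,242.90
Endosteal region,5.71E-02,7.11E-02
Brain,3.91E-02,5.48E-02
Salivary gland,1.42E-01,2.44E-01
Skin,3.77E-02,4.64E-02
Adrenal,5.18E-02,6.25E-02
ET,2.10E-01,3.31E-01
Gall bladder wall,5.08E-02,6.20E-02
Heart wall,1.23E-01,1.27E-01
Kidney,7.27E-02,8.52E-02
LN,3.27E-01,2.21E-01
Muscle,5.62E-02,7.79E-02
Oral mucosa,1.15E-01,2.47E-01
Pancreas,6.77E-02,8.24E-02
SI-wall,2.32E-01,2.67E-01
Spleen,6.31E-02,7.69E-02
Thymus,1.15,1.03
Prostate/Uterus,6.34E-02,8.03E-02
Tongue,1.35E-01,2.68E-01
Tonsils,9.20E-02,1.97E-01
LN-ET,6.25E-01,6.94E-01
LN-Th,1.84,3.25
Eye lenses,3.16E-02,4.99E-02
Pituitary gland,7.99E-02,9.78E-02
Spinal cord,2.47E-01,3.18E-01
Ureters,5.66E-02,6.26E-02
Adipose,6.44E-02,5.99E-02
Trachea,2.75,3.20
Bronchi,1.53E-01,1.74E-01
Gall bladder contents,4.82E-02,5.99E-02
Cartilage,2.05E-01,1.03E-01
Heart contents,1.05E-01,1.04E-01
Remainder tissues,2.05E-01,2.23E-01
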
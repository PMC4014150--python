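# Published organ doses (mGy/MBq) for 123I sodium iodide at 15% thyroid
# uptake in the adult male/female reference voxel phantoms.
organ,male_mGy_per_MBq,female_mGy_per_MBq
Active red marrow,9.18E-03,1.12E-02
Colon,1.22E-02,1.25E-02
Lungs,1.14E-02,1.27E-02
Stomach wall,7.76E-02,8.36E-02
Breasts,4.62E-03,5.59E-03
Testes/Ovaries,4.67E-03,1.70E-02
Urinary bladder wall,4.06E-02,4.20E-02
Esophagus,3.49E-02,4.10E-02
Liver,8.72E-03,1.04E-02
Thyroid,1.78,2.08
Endosteal region,5.79E-03,7.33E-03
Brain,3.72E-03,4.47E-03
Salivary gland,5.50E-03,8.75E-03
Skin,3.59E-03,4.45E-03
Adrenal,1.07E-02,1.30E-02
ET,7.93E-03,1.19E-02
Gall bladder wall,9.06E-03,1.32E-02
Heart wall,1.18E-02,1.11E-02
Kidney,1.36E-02,1.70E-02
LN,1.74E-02,1.69E-02
Muscle,5.58E-03,7.11E-03
Oral mucosa,5.11E-03,8.85E-03
Pancreas,1.75E-02,2.26E-02
SI-wall,3.49E-02,4.21E-02
Spleen,1.21E-02,1.85E-02
Thymus,3.50E-02,3.43E-02
Prostate/Uterus,1.81E-02,2.28E-02
Tongue,6.00E-03,9.60E-03
Tonsils,5.12E-03,7.68E-03
LN-ET,2.04E-02,2.25E-02
LN-Th,5.30E-02,8.20E-02
Eye lenses,1.91E-03,4.24E-03
Pituitary gland,2.94E-03,4.69E-03
Spinal cord,9.41E-03,1.15E-02
Ureters,1.47E-02,1.70E-02
Adipose,6.09E-03,5.91E-03
Trachea,8.74E-02,1.05E-01
Bronchi,9.33E-03,1.02E-02
Gall bladder contents,9.17E-03,1.26E-02
Cartilage,1.15E-02,8.33E-03
Heart contents,1.11E-02,1.12E-02
Remainder tissues,1.54E-02,1.87E-02
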
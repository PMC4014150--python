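# Published organ doses (mGy/MBq) for intravenous 99mTc pertechnetate in the
# adult male/female reference voxel phantoms.
organ,male_mGy_per_MBq,female_mGy_per_MBq
Active red marrow,4.23E-03,5.35E-03
Colon,2.72E-02,2.98E-02
Lungs,4.31E-03,4.51E-03
Stomach wall,2.60E-02,2.59E-02
Breasts,2.20E-03,2.36E-03
Testes/Ovaries,2.42E-03,8.60E-03
Bladder wall,1.05E-02,1.22E-02
Esophagus,4.09E-03,3.83E-03
Liver,5.70E-03,4.80E-03
Thyroid,2.20E-02,2.65E-02
Endosteal region,2.75E-03,3.55E-03
Brain,1.81E-03,2.08E-03
Salivary gland,8.42E-03,1.06E-02
Skin,1.74E-03,2.05E-03
Adrenal,5.47E-03,5.75E-03
ET,1.82E-03,2.50E-03
Gall bladder wall,8.91E-03,6.11E-03
Heart wall,4.44E-03,4.06E-03
Kidney,7.09E-03,7.57E-03
LN,5.94E-03,6.84E-03
Muscle,2.68E-03,3.47E-03
Oral mucosa,2.01E-03,2.38E-03
Pancreas,1.05E-02,9.51E-03
SI-wall,8.95E-03,1.15E-02
Spleen,5.30E-03,5.95E-03
Thymus,2.92E-03,3.14E-03
Prostate/Uterus,6.10E-03,9.92E-03
Tongue,2.13E-03,2.74E-03
Tonsils,2.19E-03,2.46E-03
LN-ET,2.32E-03,3.39E-03
LN-Th,3.57E-03,3.94E-03
Eye lenses,1.26E-03,1.19E-03
Pituitary gland,2.45E-03,1.90E-03
Spinal cord,3.12E-03,3.26E-03
Ureters,7.53E-03,9.95E-03
Adipose,3.12E-03,3.07E-03
Trachea,3.40E-03,3.91E-03
Bronchi,3.56E-03,3.44E-03
Gall Bladder contents,9.57E-03,6.13E-03
Cartilage,3.59E-03,3.70E-03
Heart contents,4.49E-03,4.23E-03
Remainder tissues,5.54E-03,6.04E-03
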
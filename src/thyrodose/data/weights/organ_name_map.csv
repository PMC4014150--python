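# Mapping from reference dose-table organ labels to ICRP-103 weighted tissues
# (gonads = testes in the male column, ovaries in the female column; the
# prostate/uterus row enters the remainder). Unlisted organs are unweighted.
organ,tissue
Active red marrow,red_marrow
Colon,colon
Lungs,lung
Stomach wall,stomach
Breasts,breast
Testes/Ovaries,gonads
Urinary bladder wall,bladder
Bladder wall,bladder
Esophagus,esophagus
Liver,liver
Thyroid,thyroid
Endosteal region,bone_surface
Brain,brain
Salivary gland,salivary_glands
Skin,skin
Adrenal,adrenals
ET,extrathoracic_region
Gall bladder wall,gall_bladder_wall
Heart wall,heart_wall
Kidney,kidneys
LN,lymphatic_nodes
Muscle,muscle
Oral mucosa,oral_mucosa
Pancreas,pancreas
SI-wall,small_intestine_wall
Spleen,spleen
Thymus,thymus
Prostate/Uterus,prostate_or_uterus
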
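# ICRP Publication 103 tissue weighting factors.
# The "remainder" row carries the shared remainder weight; rows flagged
# is_remainder=1 enter as the arithmetic mean of those tissues.
tissue,w_T,is_remainder
red_marrow,0.12,0
colon,0.12,0
lung,0.12,0
stomach,0.12,0
breast,0.12,0
remainder,0.12,0
gonads,0.08,0
bladder,0.04,0
esophagus,0.04,0
liver,0.04,0
thyroid,0.04,0
bone_surface,0.01,0
brain,0.01,0
salivary_glands,0.01,0
skin,0.01,0
adrenals,0.0,1
extrathoracic_region,0.0,1
gall_bladder_wall,0.0,1
heart_wall,0.0,1
kidneys,0.0,1
lymphatic_nodes,0.0,1
muscle,0.0,1
oral_mucosa,0.0,1
pancreas,0.0,1
prostate_or_uterus,0.0,1
small_intestine_wall,0.0,1
spleen,0.0,1
thymus,0.0,1
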
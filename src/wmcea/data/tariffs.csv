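item,code,tariff_eur,category
anaemia,395,1676,sae
leucopoenia,399,1704,sae
neutropenia,399,1704,sae
thrombocytopenia,397,2748,sae
lymphocytopenia,399,1704,sae
non_pulmonary_infections,423,4155,sae
neuropathy,19,1210,sae
pulmonary_toxicity,93,2229,sae
constipation,183,959,sae
diarrhoea,183,959,sae
chemotherapy_administration,410,371.00,outpatient
plasmapheresis,,438.99,outpatient
full_blood_count,,5.75,outpatient
immunoglobulin,,12.42,outpatient
ultrasound,,17.56,outpatient
chemistry,,7.31,outpatient
albumin_bilirubin,,3.96,outpatient
alkaline_phosphatase,,1.04,outpatient
alt_ast,,2.04,outpatient
total_protein,,1.13,outpatient
hematologic_visit,,20.66,outpatient
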
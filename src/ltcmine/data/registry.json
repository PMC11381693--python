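[
 {
  "condition_id": "stroke",
  "display_name": "Stroke",
  "sex_restricted": null
 },
 {
  "condition_id": "coronary_artery_disease",
  "display_name": "Coronary artery disease",
  "sex_restricted": null
 },
 {
  "condition_id": "heart_failure",
  "display_name": "Heart failure",
  "sex_restricted": null
 },
 {
  "condition_id": "peripheral_artery_disease",
  "display_name": "Peripheral artery disease",
  "sex_restricted": null
 },
 {
  "condition_id": "heart_valve_disorders",
  "display_name": "Heart valve disorders",
  "sex_restricted": null
 },
 {
  "condition_id": "arrhythmia",
  "display_name": "Arrhythmia",
  "sex_restricted": null
 },
 {
  "condition_id": "venous_thromboembolic_disease",
  "display_name": "Venous thromboembolic disease",
  "sex_restricted": null
 },
 {
  "condition_id": "aneurysm",
  "display_name": "Aneurysm",
  "sex_restricted": null
 },
 {
  "condition_id": "hypertension",
  "display_name": "Hypertension",
  "sex_restricted": null
 },
 {
  "condition_id": "diabetes",
  "display_name": "Diabetes",
  "sex_restricted": null
 },
 {
  "condition_id": "addisons_disease",
  "display_name": "Addison's disease",
  "sex_restricted": null
 },
 {
  "condition_id": "thyroid_disorders",
  "display_name": "Thyroid disorders",
  "sex_restricted": null
 },
 {
  "condition_id": "copd",
  "display_name": "Chronic obstructive pulmonary disease",
  "sex_restricted": null
 },
 {
  "condition_id": "asthma",
  "display_name": "Asthma",
  "sex_restricted": null
 },
 {
  "condition_id": "bronchiectasis",
  "display_name": "Bronchiectasis",
  "sex_restricted": null
 },
 {
  "condition_id": "parkinsons_disease",
  "display_name": "Parkinson's disease",
  "sex_restricted": null
 },
 {
  "condition_id": "epilepsy",
  "display_name": "Epilepsy",
  "sex_restricted": null
 },
 {
  "condition_id": "multiple_sclerosis",
  "display_name": "Multiple sclerosis",
  "sex_restricted": null
 },
 {
  "condition_id": "paralysis",
  "display_name": "Paralysis",
  "sex_restricted": null
 },
 {
  "condition_id": "transient_ischaemic_attack",
  "display_name": "Transient ischaemic attack",
  "sex_restricted": null
 },
 {
  "condition_id": "peripheral_neuropathy",
  "display_name": "Peripheral neuropathy",
  "sex_restricted": null
 },
 {
  "condition_id": "chronic_primary_pain",
  "display_name": "Chronic primary pain",
  "sex_restricted": null
 },
 {
  "condition_id": "solid_organ_cancers",
  "display_name": "Solid organ cancers",
  "sex_restricted": null
 },
 {
  "condition_id": "haematological_cancers",
  "display_name": "Haematological cancers",
  "sex_restricted": null
 },
 {
  "condition_id": "metastatic_cancers",
  "display_name": "Metastatic cancers",
  "sex_restricted": null
 },
 {
  "condition_id": "melanoma",
  "display_name": "Melanoma",
  "sex_restricted": null
 },
 {
  "condition_id": "benign_cerebral_tumours",
  "display_name": "Benign cerebral tumours",
  "sex_restricted": null
 },
 {
  "condition_id": "dementia",
  "display_name": "Dementia",
  "sex_restricted": null
 },
 {
  "condition_id": "schizophrenia",
  "display_name": "Schizophrenia",
  "sex_restricted": null
 },
 {
  "condition_id": "depression",
  "display_name": "Depression",
  "sex_restricted": null
 },
 {
  "condition_id": "anxiety",
  "display_name": "Anxiety",
  "sex_restricted": null
 },
 {
  "condition_id": "bipolar_disorder",
  "display_name": "Bipolar disorder",
  "sex_restricted": null
 },
 {
  "condition_id": "drug_alcohol_misuse",
  "display_name": "Drug/alcohol misuse",
  "sex_restricted": null
 },
 {
  "condition_id": "eating_disorder",
  "display_name": "Eating disorder",
  "sex_restricted": null
 },
 {
  "condition_id": "post_traumatic_stress_disorder",
  "display_name": "Post-traumatic stress disorder",
  "sex_restricted": null
 },
 {
  "condition_id": "connective_tissue_disease",
  "display_name": "Connective tissue disease",
  "sex_restricted": null
 },
 {
  "condition_id": "osteoarthritis",
  "display_name": "Osteoarthritis",
  "sex_restricted": null
 },
 {
  "condition_id": "musculoskeletal_injury",
  "display_name": "Long-term musculoskeletal problems due to injury",
  "sex_restricted": null
 },
 {
  "condition_id": "osteoporosis",
  "display_name": "Osteoporosis",
  "sex_restricted": null
 },
 {
  "condition_id": "gout",
  "display_name": "Gout",
  "sex_restricted": null
 },
 {
  "condition_id": "chronic_liver_disease",
  "display_name": "Chronic liver disease",
  "sex_restricted": null
 },
 {
  "condition_id": "inflammatory_bowel_disease",
  "display_name": "Inflammatory bowel disease",
  "sex_restricted": null
 },
 {
  "condition_id": "chronic_pancreatic_disease",
  "display_name": "Chronic pancreatic disease",
  "sex_restricted": null
 },
 {
  "condition_id": "peptic_ulcer",
  "display_name": "Peptic ulcer",
  "sex_restricted": null
 },
 {
  "condition_id": "chronic_kidney_disease",
  "display_name": "Chronic kidney disease",
  "sex_restricted": null
 },
 {
  "condition_id": "end_stage_kidney_disease",
  "display_name": "End-stage kidney disease",
  "sex_restricted": null
 },
 {
  "condition_id": "endometriosis",
  "display_name": "Endometriosis",
  "sex_restricted": "female"
 },
 {
  "condition_id": "anaemia",
  "display_name": "Anaemia",
  "sex_restricted": null
 },
 {
  "condition_id": "uncorrectable_vision_problems",
  "display_name": "Uncorrectable vision problems",
  "sex_restricted": null
 },
 {
  "condition_id": "menieres_disease",
  "display_name": "Meniere's disease",
  "sex_restricted": null
 },
 {
  "condition_id": "hiv_aids",
  "display_name": "HIV/AIDS",
  "sex_restricted": null
 },
 {
  "condition_id": "tuberculosis",
  "display_name": "Tuberculosis",
  "sex_restricted": null
 },
 {
  "condition_id": "congenital_disease",
  "display_name": "Congenital disease and chromosomal abnormalities",
  "sex_restricted": null
 }
]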
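"""Published semaglutide spontaneous-reporting count columns.

Reference counts from public semaglutide surveillance over 2018Q1-2023Q2:
19,289 FAERS cases and 422 coded social-media reviews, with the
corresponding system-organ-class event counts overall and split by
formulation cohort (2,508 oral / 16,711 subcutaneous cases). These serve
as worked-example inputs for the percentage conventions of the
descriptive tables; they are inputs, not outputs, of this package.
"""

N_FAERS_CASES = 19289
N_SOCIAL_REVIEWS = 422

FAERS_YEAR_COUNTS = {
    "2018": 1114,
    "2019": 1357,
    "2020": 2779,
    "2021": 4075,
    "2022": 6207,
    "2023H1": 3757,
}

FAERS_AGE_COUNTS = {"<35": 484, "35-65": 5713, ">65": 4106, "unknown": 8986}
SOCIAL_AGE_COUNTS = {"<35": 25, "35-65": 312, ">65": 80, "unknown": 5}

FAERS_SEX_COUNTS = {"male": 6896, "female": 11689, "unknown": 704}
SOCIAL_SEX_COUNTS = {"male": 93, "female": 318, "unknown": 11}

FAERS_SOC_EVENT_COUNTS = {
    "Gastrointestinal disorders": 15704,
    "General disorders and administration site conditions": 6787,
    "Injury, poisoning and procedural complications": 6093,
    "Investigations": 4780,
    "Nervous system disorders": 4047,
    "Metabolism and nutrition disorders": 3525,
    "Skin and subcutaneous tissue disorders": 1878,
    "Eye disorders": 1544,
    "Psychiatric disorders": 1531,
    "Musculoskeletal and connective tissue disorders": 1477,
    "Product issues": 1320,
    "Infections and infestations": 1304,
    "Respiratory, thoracic and mediastinal disorders": 1023,
    "Renal and urinary disorders": 881,
    "Cardiac disorders": 661,
    "Hepatobiliary disorders": 628,
    "Surgical and medical procedures": 620,
    "Neoplasms benign, malignant and unspecified (incl cysts and polyps)": 563,
    "Vascular disorders": 477,
    "Reproductive system and breast disorders": 263,
    "Ear and labyrinth disorders": 213,
    "Immune system disorders": 213,
    "Social circumstances": 166,
    "Endocrine disorders": 162,
    "Blood and lymphatic system disorders": 109,
    "Pregnancy, puerperium and perinatal conditions": 62,
    "Congenital, familial and genetic disorders": 17,
}

SOCIAL_SOC_EVENT_COUNTS = {
    "Gastrointestinal disorders": 864,
    "General disorders and administration site conditions": 128,
    "Respiratory, thoracic and mediastinal disorders": 114,
    "Nervous system disorders": 99,
    "Metabolism and nutrition disorders": 72,
    "Psychiatric disorders": 30,
    "Musculoskeletal and connective tissue disorders": 12,
    "Skin and subcutaneous tissue disorders": 11,
    "Investigations": 8,
    "Eye disorders": 6,
    "Infections and infestations": 5,
    "Cardiac disorders": 2,
    "Renal and urinary disorders": 2,
    "Blood and lymphatic system disorders": 1,
    "Ear and labyrinth disorders": 1,
    "Hepatobiliary disorders": 1,
    "Immune system disorders": 1,
    "Vascular disorders": 1,
}

ORAL_SOC_EVENT_COUNTS = {
    "Gastrointestinal disorders": 1792,
    "General disorders and administration site conditions": 580,
    "Investigations": 579,
    "Nervous system disorders": 491,
    "Metabolism and nutrition disorders": 359,
    "Injury, poisoning and procedural complications": 327,
    "Skin and subcutaneous tissue disorders": 271,
    "Eye disorders": 205,
    "Musculoskeletal and connective tissue disorders": 190,
    "Respiratory, thoracic and mediastinal disorders": 151,
    "Psychiatric disorders": 132,
    "Renal and urinary disorders": 124,
    "Infections and infestations": 123,
    "Hepatobiliary disorders": 94,
    "Cardiac disorders": 87,
    "Product issues": 86,
    "Surgical and medical procedures": 80,
    "Neoplasms benign, malignant and unspecified (incl cysts and polyps)": 70,
    "Vascular disorders": 54,
    "Immune system disorders": 35,
    "Reproductive system and breast disorders": 29,
    "Endocrine disorders": 22,
    "Ear and labyrinth disorders": 17,
    "Blood and lymphatic system disorders": 14,
    "Social circumstances": 12,
    "Pregnancy, puerperium and perinatal conditions": 7,
    "Congenital, familial and genetic disorders": 5,
}

SUBCUT_SOC_EVENT_COUNTS = {
    "Gastrointestinal disorders": 13857,
    "General disorders and administration site conditions": 6192,
    "Injury, poisoning and procedural complications": 5751,
    "Investigations": 4196,
    "Nervous system disorders": 3545,
    "Metabolism and nutrition disorders": 3149,
    "Skin and subcutaneous tissue disorders": 1604,
    "Psychiatric disorders": 1392,
    "Eye disorders": 1333,
    "Musculoskeletal and connective tissue disorders": 1286,
    "Product issues": 1230,
    "Infections and infestations": 1170,
    "Respiratory, thoracic and mediastinal disorders": 858,
    "Renal and urinary disorders": 753,
    "Cardiac disorders": 565,
    "Surgical and medical procedures": 536,
    "Hepatobiliary disorders": 528,
    "Neoplasms benign, malignant and unspecified (incl cysts and polyps)": 493,
    "Vascular disorders": 420,
    "Reproductive system and breast disorders": 234,
    "Ear and labyrinth disorders": 195,
    "Immune system disorders": 175,
    "Social circumstances": 152,
    "Endocrine disorders": 140,
    "Blood and lymphatic system disorders": 92,
    "Pregnancy, puerperium and perinatal conditions": 52,
    "Congenital, familial and genetic disorders": 12,
}
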
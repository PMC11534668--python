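pt	soc
Nausea	Gastrointestinal disorders
Vomiting	Gastrointestinal disorders
Diarrhoea	Gastrointestinal disorders
Constipation	Gastrointestinal disorders
Abdominal pain upper	Gastrointestinal disorders
Abdominal pain	Gastrointestinal disorders
Abdominal distension	Gastrointestinal disorders
Abdominal discomfort	Gastrointestinal disorders
Eructation	Gastrointestinal disorders
Flatulence	Gastrointestinal disorders
Dyspepsia	Gastrointestinal disorders
Pancreatitis	Gastrointestinal disorders
Gastrooesophageal reflux disease	Gastrointestinal disorders
Hiccups	Gastrointestinal disorders
Heartburn	Gastrointestinal disorders
Gastrointestinal pain	Gastrointestinal disorders
Diarrhoea haemorrhagic	Gastrointestinal disorders
Pancreatic failure	Gastrointestinal disorders
Gastric emptying impaired	Gastrointestinal disorders
Fatigue	General disorders and administration site conditions
Malaise	General disorders and administration site conditions
Asthenia	General disorders and administration site conditions
Drug ineffective	General disorders and administration site conditions
Influenza like illness	General disorders and administration site conditions
Injection site extravasation	General disorders and administration site conditions
Injection site pain	General disorders and administration site conditions
Weight decreased	Investigations
Blood glucose increased	Investigations
Blood glucose decreased	Investigations
Hormone level abnormal	Investigations
Lipase increased	Investigations
Headache	Nervous system disorders
Dizziness	Nervous system disorders
Somnolence	Nervous system disorders
Lethargy	Nervous system disorders
Dysgeusia	Nervous system disorders
Decreased appetite	Metabolism and nutrition disorders
Dehydration	Metabolism and nutrition disorders
Hypoglycaemia	Metabolism and nutrition disorders
Wrong technique in product usage process	Injury, poisoning and procedural complications
Inappropriate schedule of product administration	Injury, poisoning and procedural complications
Product use in unapproved indication	Injury, poisoning and procedural complications
Accidental overdose	Injury, poisoning and procedural complications
Fall	Injury, poisoning and procedural complications
Device malfunction	Product issues
Device leakage	Product issues
Needle issue	Product issues
Vision blurred	Eye disorders
Diplopia	Eye disorders
Insomnia	Psychiatric disorders
Anxiety	Psychiatric disorders
Depression	Psychiatric disorders
Injection phobia	Psychiatric disorders
Rash	Skin and subcutaneous tissue disorders
Alopecia	Skin and subcutaneous tissue disorders
Pruritus	Skin and subcutaneous tissue disorders
Myalgia	Musculoskeletal and connective tissue disorders
Back pain	Musculoskeletal and connective tissue disorders
Dupuytren's contracture	Musculoskeletal and connective tissue disorders
Arthralgia	Musculoskeletal and connective tissue disorders
Hepatic pain	Hepatobiliary disorders
Cholelithiasis	Hepatobiliary disorders
Palpitations	Cardiac disorders
Tachycardia	Cardiac disorders
Acute kidney injury	Renal and urinary disorders
Dyspnoea	Respiratory, thoracic and mediastinal disorders
Cough	Respiratory, thoracic and mediastinal disorders
Nasopharyngitis	Infections and infestations
Urinary tract infection	Infections and infestations
Pancreatic carcinoma	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Thyroid neoplasm	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
Hypertension	Vascular disorders
Hypotension	Vascular disorders
Hypersensitivity	Immune system disorders
Goitre	Endocrine disorders
Anaemia	Blood and lymphatic system disorders
Vertigo	Ear and labyrinth disorders
Tinnitus	Ear and labyrinth disorders
Erectile dysfunction	Reproductive system and breast disorders
Cholecystectomy	Surgical and medical procedures
Off label use	Injury, poisoning and procedural complications
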
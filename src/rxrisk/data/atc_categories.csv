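atc_prefix,category_id,category_name
N07BB,alcohol_dependence,Alcohol dependence
R06A,allergy,Allergies
B01AA,anticoagulant,Anticoagulants
B01AB,anticoagulant,Anticoagulants
B01AE,anticoagulant,Anticoagulants
B01AF,anticoagulant,Anticoagulants
B01AC,antiplatelet,Antiplatelet agents
N05BA,anxiety,Anxiety
N05BE,anxiety,Anxiety
C01AA,arrhythmia,Arrhythmia
C01B,arrhythmia,Arrhythmia
G04CA,bph,Benign prostatic hyperplasia
G04CB,bph,Benign prostatic hyperplasia
N05AN,bipolar_disorder,Bipolar disorder
R03,chronic_airways_disease,Chronic airways disease
C03DA,congestive_heart_failure,Congestive heart failure
N06D,dementia,Dementia
N06A,depression,Depression
A10,diabetes,Diabetes
N03A,epilepsy,Epilepsy
A02B,gerd,Gastro-oesophageal reflux disease
S01E,glaucoma,Glaucoma
M04A,gout,Gout
J05AF,hepatitis_b,Hepatitis B
J05AP,hepatitis_c,Hepatitis C
J05AR,hiv,HIV
J05AG,hiv,HIV
J05AE,hiv,HIV
V03AE,hyperkalaemia,Hyperkalaemia
C10,hyperlipidaemia,Hyperlipidaemia
C02A,hypertension,Hypertension
C02C,hypertension,Hypertension
C03A,hypertension,Hypertension
C03B,hypertension,Hypertension
C03C,hypertension,Hypertension
C09,hypertension,Hypertension
H03B,hyperthyroidism,Hyperthyroidism
H03A,hypothyroidism,Hypothyroidism
A07E,inflammatory_bowel_disease,Inflammatory bowel disease
A03AA,irritable_bowel_syndrome,Irritable bowel syndrome
A03AB,irritable_bowel_syndrome,Irritable bowel syndrome
G04BD,incontinence,Urinary incontinence
C01DA,ihd_angina,Ischaemic heart disease: angina
C07,ihd_hypertension,Ischaemic heart disease: beta blockade
C08,ihd_hypertension,Ischaemic heart disease: beta blockade
L01,malignancy,Malignancies
N02C,migraine,Migraine
M05B,osteoporosis,Osteoporosis and Paget's disease
N02A,pain,Pain
N02BE,pain,Pain
M01A,pain,Pain
N04,parkinsons_disease,Parkinson's disease
D05,psoriasis,Psoriasis
N05A,psychotic_illness,Psychotic illness
C02K,pulmonary_hypertension,Pulmonary hypertension
B03XA,renal_disease,Chronic renal disease
N07BA,smoking_cessation,Smoking cessation
H02AB,steroid_responsive,Steroid-responsive disease
L04AA,transplant,Transplantation
J04A,tuberculosis,Tuberculosis
N05C,insomnia,Insomnia
A09A,pancreatic_insufficiency,Pancreatic insufficiency
N06BA,adhd,Attention deficit hyperactivity disorder
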
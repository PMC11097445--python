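# SYNTHETIC demo disease list (60 condition groups).
# The condition groups and code prefixes below are illustrative
# stand-ins with the correct list size, not a validated code set;
# supply your own YAML in the same schema for real analyses.
name: L60
conditions:
- id: hypertension
  label: Hypertension
  icd9:
  - '401'
  icd10:
  - I10
- id: diabetes
  label: Diabetes mellitus
  icd9:
  - '250'
  icd10:
  - E11
- id: ischemic_heart_disease
  label: Ischemic heart disease
  icd9:
  - '414'
  icd10:
  - I25
- id: heart_failure
  label: Heart failure
  icd9:
  - '428'
  icd10:
  - I50
- id: stroke
  label: Cerebrovascular disease
  icd9:
  - '434'
  icd10:
  - I63
- id: copd
  label: Chronic obstructive pulmonary disease
  icd9:
  - '496'
  icd10:
  - J44
- id: asthma
  label: Asthma
  icd9:
  - '493'
  icd10:
  - J45
- id: chronic_kidney_disease
  label: Chronic kidney disease
  icd9:
  - '585'
  icd10:
  - N18
- id: depression
  label: Depressive disorders
  icd9:
  - '311'
  icd10:
  - F32
  mental: true
  remitting: true
- id: anxiety_disorder
  label: Anxiety disorders
  icd9:
  - '300'
  icd10:
  - F41
  mental: true
  remitting: true
- id: dementia
  label: Dementia
  icd9:
  - '290'
  icd10:
  - F03
- id: osteoporosis
  label: Osteoporosis
  icd9:
  - '733'
  icd10:
  - M81
- id: osteoarthritis
  label: Osteoarthritis
  icd9:
  - '715'
  icd10:
  - M15
- id: rheumatoid_arthritis
  label: Rheumatoid arthritis
  icd9:
  - '714'
  icd10:
  - M05
- id: cancer_lung
  label: Lung cancer
  icd9:
  - '162'
  icd10:
  - C34
- id: cancer_breast
  label: Breast cancer
  icd9:
  - '174'
  icd10:
  - C50
- id: cancer_colorectal
  label: Colorectal cancer
  icd9:
  - '153'
  icd10:
  - C18
- id: cancer_prostate
  label: Prostate cancer
  icd9:
  - '185'
  icd10:
  - C61
- id: lymphoma
  label: Lymphoma
  icd9:
  - '202'
  icd10:
  - C85
- id: leukemia
  label: Leukemia
  icd9:
  - '204'
  icd10:
  - C91
- id: parkinsons_disease
  label: Parkinson's disease
  icd9:
  - '332'
  icd10:
  - G20
- id: epilepsy
  label: Epilepsy
  icd9:
  - '345'
  icd10:
  - G40
- id: multiple_sclerosis
  label: Multiple sclerosis
  icd9:
  - '340'
  icd10:
  - G35
- id: schizophrenia
  label: Schizophrenia and psychotic disorders
  icd9:
  - '295'
  icd10:
  - F20
  mental: true
  remitting: true
- id: bipolar_disorder
  label: Bipolar disorder
  icd9:
  - '296'
  icd10:
  - F31
  mental: true
  remitting: true
- id: substance_use_disorder
  label: Substance use disorder
  icd9:
  - '304'
  icd10:
  - F19
  mental: true
  remitting: true
- id: alcohol_use_disorder
  label: Alcohol use disorder
  icd9:
  - '303'
  icd10:
  - F10
  mental: true
  remitting: true
- id: cirrhosis
  label: Cirrhosis and chronic liver disease
  icd9:
  - '571'
  icd10:
  - K74
- id: chronic_viral_hepatitis
  label: Chronic viral hepatitis
  icd9:
  - '070'
  icd10:
  - B18
- id: chronic_pancreatitis
  label: Chronic pancreatitis
  icd9:
  - '577'
  icd10:
  - K86
- id: inflammatory_bowel_disease
  label: Inflammatory bowel disease
  icd9:
  - '555'
  icd10:
  - K50
- id: peptic_ulcer_disease
  label: Peptic ulcer disease
  icd9:
  - '533'
  icd10:
  - K27
- id: diverticular_disease
  label: Diverticular disease
  icd9:
  - '562'
  icd10:
  - K57
- id: atrial_fibrillation
  label: Atrial fibrillation
  icd9:
  - '427'
  icd10:
  - I48
- id: valvular_heart_disease
  label: Valvular heart disease
  icd9:
  - '424'
  icd10:
  - I35
- id: peripheral_vascular_disease
  label: Peripheral vascular disease
  icd9:
  - '443'
  icd10:
  - I73
- id: aortic_aneurysm
  label: Aortic aneurysm
  icd9:
  - '441'
  icd10:
  - I71
- id: pulmonary_hypertension
  label: Pulmonary hypertension
  icd9:
  - '416'
  icd10:
  - I27
- id: sleep_apnea
  label: Sleep apnea
  icd9:
  - '327'
  icd10:
  - G47
- id: hypothyroidism
  label: Hypothyroidism
  icd9:
  - '244'
  icd10:
  - E03
- id: hyperthyroidism
  label: Hyperthyroidism
  icd9:
  - '242'
  icd10:
  - E05
- id: obesity
  label: Obesity
  icd9:
  - '278'
  icd10:
  - E66
- id: dyslipidemia
  label: Dyslipidemia
  icd9:
  - '272'
  icd10:
  - E78
- id: gout
  label: Gout
  icd9:
  - '274'
  icd10:
  - M10
- id: psoriasis
  label: Psoriasis
  icd9:
  - '696'
  icd10:
  - L40
- id: chronic_skin_ulcer
  label: Chronic skin ulcer
  icd9:
  - '707'
  icd10:
  - L97
- id: glaucoma
  label: Glaucoma
  icd9:
  - '365'
  icd10:
  - H40
- id: macular_degeneration
  label: Macular degeneration
  icd9:
  - '362'
  icd10:
  - H35
- id: hearing_loss
  label: Hearing loss
  icd9:
  - '389'
  icd10:
  - H90
- id: chronic_back_pain
  label: Chronic back pain
  icd9:
  - '724'
  icd10:
  - M54
- id: fibromyalgia
  label: Fibromyalgia and chronic pain syndromes
  icd9:
  - '729'
  icd10:
  - M79
- id: migraine
  label: Migraine
  icd9:
  - '346'
  icd10:
  - G43
- id: chronic_anemia
  label: Chronic anemia
  icd9:
  - '285'
  icd10:
  - D64
- id: hiv
  label: HIV infection
  icd9:
  - '042'
  icd10:
  - B20
- id: venous_thromboembolism
  label: Venous thromboembolism
  icd9:
  - '453'
  icd10:
  - I82
- id: conduction_disorder
  label: Cardiac conduction disorder
  icd9:
  - '426'
  icd10:
  - I44
- id: bronchiectasis
  label: Bronchiectasis
  icd9:
  - '494'
  icd10:
  - J47
- id: interstitial_lung_disease
  label: Interstitial lung disease
  icd9:
  - '515'
  icd10:
  - J84
- id: cardiomyopathy
  label: Cardiomyopathy
  icd9:
  - '425'
  icd10:
  - I42
- id: cancer_bladder
  label: Bladder cancer
  icd9:
  - '188'
  icd10:
  - C67
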
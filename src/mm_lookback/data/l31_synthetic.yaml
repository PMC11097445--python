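# SYNTHETIC demo disease list (31 condition groups).
# The condition groups and code prefixes below are illustrative
# stand-ins with the correct list size, not a validated code set;
# supply your own YAML in the same schema for real analyses.
name: L31
conditions:
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
- id: peripheral_vascular_disease
  label: Peripheral vascular disease
  icd9:
  - '443'
  icd10:
  - I73
- id: stroke
  label: Cerebrovascular disease
  icd9:
  - '434'
  icd10:
  - I63
- id: dementia
  label: Dementia
  icd9:
  - '290'
  icd10:
  - F03
- id: copd
  label: Chronic obstructive pulmonary disease
  icd9:
  - '496'
  icd10:
  - J44
- id: rheumatoid_arthritis
  label: Rheumatoid arthritis
  icd9:
  - '714'
  icd10:
  - M05
- id: peptic_ulcer_disease
  label: Peptic ulcer disease
  icd9:
  - '533'
  icd10:
  - K27
- id: cirrhosis
  label: Cirrhosis and chronic liver disease
  icd9:
  - '571'
  icd10:
  - K74
- id: diabetes
  label: Diabetes mellitus
  icd9:
  - '250'
  icd10:
  - E11
- id: chronic_kidney_disease
  label: Chronic kidney disease
  icd9:
  - '585'
  icd10:
  - N18
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
- id: hiv
  label: HIV infection
  icd9:
  - '042'
  icd10:
  - B20
- id: hypertension
  label: Hypertension
  icd9:
  - '401'
  icd10:
  - I10
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
- id: pulmonary_hypertension
  label: Pulmonary hypertension
  icd9:
  - '416'
  icd10:
  - I27
- id: epilepsy
  label: Epilepsy
  icd9:
  - '345'
  icd10:
  - G40
- id: hypothyroidism
  label: Hypothyroidism
  icd9:
  - '244'
  icd10:
  - E03
- id: obesity
  label: Obesity
  icd9:
  - '278'
  icd10:
  - E66
- id: chronic_anemia
  label: Chronic anemia
  icd9:
  - '285'
  icd10:
  - D64
- id: alcohol_use_disorder
  label: Alcohol use disorder
  icd9:
  - '303'
  icd10:
  - F10
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
- id: schizophrenia
  label: Schizophrenia and psychotic disorders
  icd9:
  - '295'
  icd10:
  - F20
  mental: true
  remitting: true
- id: depression
  label: Depressive disorders
  icd9:
  - '311'
  icd10:
  - F32
  mental: true
  remitting: true
- id: venous_thromboembolism
  label: Venous thromboembolism
  icd9:
  - '453'
  icd10:
  - I82
- id: chronic_viral_hepatitis
  label: Chronic viral hepatitis
  icd9:
  - '070'
  icd10:
  - B18
- id: aortic_aneurysm
  label: Aortic aneurysm
  icd9:
  - '441'
  icd10:
  - I71
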
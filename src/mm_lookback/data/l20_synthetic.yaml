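# SYNTHETIC demo disease list (20 condition groups).
# The condition groups and code prefixes below are illustrative
# stand-ins with the correct list size, not a validated code set;
# supply your own YAML in the same schema for real analyses.
name: L20
conditions:
- id: diabetes
  label: Diabetes mellitus
  icd9:
  - '250'
  icd10:
  - E11
  disease_specific:
    min_physician_claims: 2
    min_spacing_days: 30
    max_pair_span_days: 730
- id: ischemic_heart_disease
  label: Ischemic heart disease
  icd9:
  - '414'
  icd10:
  - I25
  disease_specific:
    min_physician_claims: 2
    min_spacing_days: 30
    max_pair_span_days: 730
- id: heart_failure
  label: Heart failure
  icd9:
  - '428'
  icd10:
  - I50
  disease_specific:
    min_physician_claims: 2
    min_spacing_days: 30
    max_pair_span_days: 730
- id: stroke
  label: Cerebrovascular disease
  icd9:
  - '434'
  icd10:
  - I63
  disease_specific:
    min_physician_claims: 2
    min_spacing_days: 30
    max_pair_span_days: 730
- id: copd
  label: Chronic obstructive pulmonary disease
  icd9:
  - '496'
  icd10:
  - J44
  disease_specific:
    min_physician_claims: 2
    min_spacing_days: 30
    max_pair_span_days: 730
- id: asthma
  label: Asthma
  icd9:
  - '493'
  icd10:
  - J45
  disease_specific:
    min_physician_claims: 2
    min_spacing_days: 30
    max_pair_span_days: 730
    max_lookback_years: 3
- id: chronic_kidney_disease
  label: Chronic kidney disease
  icd9:
  - '585'
  icd10:
  - N18
  disease_specific:
    min_physician_claims: 2
    min_spacing_days: 30
    max_pair_span_days: 730
- id: depression
  label: Depressive disorders
  icd9:
  - '311'
  icd10:
  - F32
  mental: true
  remitting: true
  disease_specific:
    min_physician_claims: 2
    min_spacing_days: 30
    max_pair_span_days: 730
    max_lookback_years: 5
- id: anxiety_disorder
  label: Anxiety disorders
  icd9:
  - '300'
  icd10:
  - F41
  mental: true
  remitting: true
  disease_specific:
    min_physician_claims: 2
    min_spacing_days: 30
    max_pair_span_days: 730
    max_lookback_years: 5
- id: dementia
  label: Dementia
  icd9:
  - '290'
  icd10:
  - F03
  disease_specific:
    min_physician_claims: 2
    min_spacing_days: 30
    max_pair_span_days: 730
- id: cancer_lung
  label: Lung cancer
  icd9:
  - '162'
  icd10:
  - C34
  disease_specific:
    min_physician_claims: 2
    min_spacing_days: 30
    max_pair_span_days: 730
- id: cancer_breast
  label: Breast cancer
  icd9:
  - '174'
  icd10:
  - C50
  disease_specific:
    min_physician_claims: 2
    min_spacing_days: 30
    max_pair_span_days: 730
- id: cancer_colorectal
  label: Colorectal cancer
  icd9:
  - '153'
  icd10:
  - C18
  disease_specific:
    min_physician_claims: 2
    min_spacing_days: 30
    max_pair_span_days: 730
- id: cancer_prostate
  label: Prostate cancer
  icd9:
  - '185'
  icd10:
  - C61
  disease_specific:
    min_physician_claims: 2
    min_spacing_days: 30
    max_pair_span_days: 730
- id: osteoarthritis
  label: Osteoarthritis
  icd9:
  - '715'
  icd10:
  - M15
  disease_specific:
    min_physician_claims: 2
    min_spacing_days: 30
    max_pair_span_days: 730
- id: rheumatoid_arthritis
  label: Rheumatoid arthritis
  icd9:
  - '714'
  icd10:
  - M05
  disease_specific:
    min_physician_claims: 2
    min_spacing_days: 30
    max_pair_span_days: 730
- id: cirrhosis
  label: Cirrhosis and chronic liver disease
  icd9:
  - '571'
  icd10:
  - K74
  disease_specific:
    min_physician_claims: 2
    min_spacing_days: 30
    max_pair_span_days: 730
- id: parkinsons_disease
  label: Parkinson's disease
  icd9:
  - '332'
  icd10:
  - G20
  disease_specific:
    min_physician_claims: 2
    min_spacing_days: 30
    max_pair_span_days: 730
- id: epilepsy
  label: Epilepsy
  icd9:
  - '345'
  icd10:
  - G40
  disease_specific:
    min_physician_claims: 2
    min_spacing_days: 30
    max_pair_span_days: 730
- id: osteoporosis
  label: Osteoporosis
  icd9:
  - '733'
  icd10:
  - M81
  disease_specific:
    min_physician_claims: 2
    min_spacing_days: 30
    max_pair_span_days: 730
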
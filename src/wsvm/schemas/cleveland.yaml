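# Declarative feature metadata for the UCI Cleveland heart-disease table
# (processed.cleveland.data dialect: 13 predictors + the "num" response,
# comma-separated, "?" marks a missing cell).
#
# kind: continuous  -> real-valued covariate, enters the matrix as-is
# kind: categorical -> integer-coded factor; "codes" lists the permitted codes
#
# CA (number of major vessels coloured by fluoroscopy) is an ordered count
# 0-3 and is treated as numeric; THAL keeps its historical codes 3/6/7.
response: num
missing_marker: "?"
features:
  - name: AGE
    kind: continuous
    description: patient age in years
  - name: SEX
    kind: categorical
    codes: [0, 1]
    description: patient sex (1 = male, 0 = female)
  - name: CP
    kind: categorical
    codes: [1, 2, 3, 4]
    description: chest pain type (1 typical angina ... 4 asymptomatic)
  - name: RBP
    kind: continuous
    description: resting blood pressure (mm Hg)
  - name: CHOL
    kind: continuous
    description: serum cholesterol (mg/dL)
  - name: FBS
    kind: categorical
    codes: [0, 1]
    description: fasting blood sugar > 120 mg/dL (1 yes, 0 no)
  - name: RECGR
    kind: categorical
    codes: [0, 1, 2]
    description: resting ECG result (0 normal, 1 ST-T abnormality, 2 LV hypertrophy)
  - name: MHRA
    kind: continuous
    description: maximum heart rate achieved
  - name: EXANG
    kind: categorical
    codes: [0, 1]
    description: exercise-induced angina (1 yes, 0 no)
  - name: OLDPK
    kind: continuous
    description: ST depression induced by exercise relative to rest
  - name: SLOPE
    kind: categorical
    codes: [1, 2, 3]
    description: slope of the peak-exercise ST segment
  - name: CA
    kind: continuous
    description: number of major vessels coloured by fluoroscopy (0-3)
  - name: THAL
    kind: categorical
    codes: [3, 6, 7]
    description: thallium stress-test defect (3 normal, 6 fixed, 7 reversible)
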
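# Default disease-attribute registry: 13 acute events, 7 subacute disorders
# (including chronic pain), 6 chronic disorders, plus therapy-specific
# complication attributes.
#
# ICD-9/ICD-10 code lists are ILLUSTRATIVE placeholders chosen to be plausible
# for each condition; they are not a clinically validated mapping and are fully
# overridable by a user-supplied registry file.
attributes:
  # ---- acute events (instantaneous) ----
  - name: vaso_occlusive_pain_episodes
    dimension: acute_event
    persistence: instantaneous
    icd9: ["282.62", "282.64", "282.69"]
    icd10: ["D57.00", "D57.219", "D57.419"]
    severity_marker: true
  - name: stroke
    dimension: acute_event
    persistence: instantaneous
    icd9: ["434.91"]
    icd10: ["I63.9"]
    severity_marker: true
  - name: fever
    dimension: acute_event
    persistence: instantaneous
    icd9: ["780.60"]
    icd10: ["R50.9"]
  - name: splenic_disease
    dimension: acute_event
    persistence: instantaneous
    icd9: ["289.52"]
    icd10: ["D73.5"]
  - name: priapism
    dimension: acute_event
    persistence: instantaneous
    icd9: ["607.3"]
    icd10: ["N48.30"]
  - name: dactylitis
    dimension: acute_event
    persistence: instantaneous
    icd9: ["729.89"]
    icd10: ["M79.89"]
  - name: acute_chest_syndrome
    dimension: acute_event
    persistence: instantaneous
    icd9: ["517.3"]
    icd10: ["J80"]
    severity_marker: true
  - name: myocardial_infarction
    dimension: acute_event
    persistence: instantaneous
    icd9: ["410.91"]
    icd10: ["I21.9"]
  - name: infections
    dimension: acute_event
    persistence: instantaneous
    icd9: ["486", "599.0"]
    icd10: ["J18.9", "N39.0"]
  - name: acute_renal_failure
    dimension: acute_event
    persistence: instantaneous
    icd9: ["584.9"]
    icd10: ["N17.9"]
  - name: multi_organ_failure
    dimension: acute_event
    persistence: instantaneous
    icd9: ["995.92"]
    icd10: ["R65.11"]
    severity_marker: true
  - name: bacteremia_and_sepsis
    dimension: acute_event
    persistence: instantaneous
    icd9: ["038.9", "790.7"]
    icd10: ["A41.9", "R78.81"]
  - name: acute_anemia
    dimension: acute_event
    persistence: instantaneous
    icd9: ["285.1"]
    icd10: ["D62"]
  # ---- subacute disorders (remitting; 2-year claim lookback) ----
  - name: chronic_pain
    dimension: chronic_pain
    persistence: subacute
    icd9: ["338.29"]
    icd10: ["G89.29"]
  - name: fatigue
    dimension: chronic_disorder
    persistence: subacute
    icd9: ["780.79"]
    icd10: ["R53.83"]
  - name: asthma
    dimension: chronic_disorder
    persistence: subacute
    icd9: ["493.90"]
    icd10: ["J45.909"]
  - name: leg_ulcers
    dimension: chronic_disorder
    persistence: subacute
    icd9: ["707.10"]
    icd10: ["L97.909"]
  - name: hepatobiliary_complications_and_liver_disease
    dimension: chronic_disorder
    persistence: subacute
    icd9: ["574.20", "571.9"]
    icd10: ["K80.20", "K76.9"]
  - name: sleep_disordered_breathing
    dimension: chronic_disorder
    persistence: subacute
    icd9: ["327.23"]
    icd10: ["G47.33"]
  - name: depression_and_unspecified_psychosis
    dimension: chronic_disorder
    persistence: subacute
    icd9: ["311", "298.9"]
    icd10: ["F32.9", "F29"]
  # ---- chronic disorders (absorbing) ----
  - name: chronic_renal_disease
    dimension: chronic_disorder
    persistence: chronic
    icd9: ["585.9"]
    icd10: ["N18.9"]
  - name: pulmonary_hypertension_and_cardiovascular_diseases
    dimension: chronic_disorder
    persistence: chronic
    icd9: ["416.0", "428.0"]
    icd10: ["I27.0", "I50.9"]
  - name: chronic_lung_diseases
    dimension: chronic_disorder
    persistence: chronic
    icd9: ["496"]
    icd10: ["J44.9"]
  - name: ocular_complications
    dimension: chronic_disorder
    persistence: chronic
    icd9: ["362.29"]
    icd10: ["H35.89"]
  - name: cognitive_impairment
    dimension: chronic_disorder
    persistence: chronic
    icd9: ["331.83"]
    icd10: ["G31.84"]
  - name: avascular_necrosis_and_bone_damage
    dimension: chronic_disorder
    persistence: chronic
    icd9: ["733.40"]
    icd10: ["M87.9"]
  # ---- treatment complications ----
  - name: leukopenia
    dimension: treatment_complication
    persistence: subacute
    icd9: ["288.50"]
    icd10: ["D72.819"]
  - name: thrombocytopenia
    dimension: treatment_complication
    persistence: subacute
    icd9: ["287.5"]
    icd10: ["D69.6"]
  - name: oligospermia_azospermia
    dimension: treatment_complication
    persistence: chronic
    icd9: ["606.1"]
    icd10: ["N46.11"]
  - name: iron_overload
    dimension: treatment_complication
    persistence: chronic
    icd9: ["275.02"]
    icd10: ["E83.111"]
  - name: transfusion_reaction
    dimension: treatment_complication
    persistence: subacute
    icd9: ["999.80"]
    icd10: ["T80.92"]
  - name: transfusion_infection
    dimension: treatment_complication
    persistence: subacute
    icd9: ["999.39"]
    icd10: ["T80.29"]
  - name: graft_versus_host_disease
    dimension: treatment_complication
    persistence: chronic
    icd9: ["279.50"]
    icd10: ["D89.813"]
  - name: graft_failure
    dimension: treatment_complication
    persistence: chronic
    icd9: ["996.85"]
    icd10: ["T86.5"]
  - name: bronchiolitis_obliterans
    dimension: treatment_complication
    persistence: chronic
    icd9: ["491.8"]
    icd10: ["J44.81"]
  - name: osteoporosis
    dimension: treatment_complication
    persistence: chronic
    icd9: ["733.00"]
    icd10: ["M81.0"]
  - name: post_treatment_depression
    dimension: treatment_complication
    persistence: subacute
    icd9: ["309.0"]
    icd10: ["F43.21"]
  - name: posterior_reversible_encephalopathy_syndrome
    dimension: treatment_complication
    persistence: subacute
    icd9: ["348.39"]
    icd10: ["I67.83"]
  - name: post_transplant_lymphoproliferative_disorder
    dimension: treatment_complication
    persistence: chronic
    icd9: ["238.77"]
    icd10: ["D47.Z1"]
  - name: secondary_malignancy
    dimension: treatment_complication
    persistence: chronic
    icd9: ["199.1"]
    icd10: ["C80.1"]

therapies:
  hydroxyurea:
    - leukopenia
    - thrombocytopenia
    - oligospermia_azospermia
  transfusion:
    - iron_overload
    - transfusion_reaction
    - transfusion_infection
  hsct:
    - graft_versus_host_disease
    - graft_failure
    - bronchiolitis_obliterans
    - osteoporosis
    - iron_overload
    - post_treatment_depression
    - posterior_reversible_encephalopathy_syndrome
    - post_transplant_lymphoproliferative_disorder
    - secondary_malignancy
  gene_therapy:
    - graft_failure
    - bronchiolitis_obliterans
    - osteoporosis
    - iron_overload
    - post_treatment_depression
    - posterior_reversible_encephalopathy_syndrome
    - post_transplant_lymphoproliferative_disorder
    - secondary_malignancy

scd_case_definition:
  icd9:
    include: ["282.6", "282.41", "282.42"]
    exclude: ["282.5"]
  icd10:
    include: ["D57"]
    exclude: ["D57.3"]
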
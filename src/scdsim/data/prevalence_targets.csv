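attribute,medicaid,medicare,dual,combined
vaso_occlusive_pain_episodes,78.1,42.4,71.8,72.5
stroke,9.1,21.4,15.4,12.9
fever,61.4,29.5,55.6,56.3
splenic_disease,11.7,5.8,8.6,9.8
priapism,3.5,1.0,3.9,3.5
dactylitis,2.9,5.0,5.1,4.1
acute_chest_syndrome,31.6,15.6,32.0,30.5
myocardial_infarction,0.9,5.7,3.8,2.5
infections,79.4,73.0,82.1,80.1
acute_renal_failure,7.9,30.9,22.4,16.2
multi_organ_failure,2.0,5.6,6.0,4.0
bacteremia_and_sepsis,17.5,20.1,28.4,22.6
acute_anemia,8.5,5.4,10.4,9.1
chronic_pain,18.0,31.0,39.6,28.7
fatigue,20.2,57.4,44.7,34.0
asthma,36.5,24.3,37.1,35.8
leg_ulcers,0.9,3.9,3.1,2.1
hepatobiliary_complications_and_liver_disease,19.2,22.6,25.5,22.3
sleep_disordered_breathing,25.8,29.6,32.5,29.1
depression_and_unspecified_psychosis,15.1,28.3,32.3,23.8
chronic_renal_disease,14.2,54.0,35.1,26.6
pulmonary_hypertension_and_cardiovascular_diseases,35.5,71.1,59.6,49.0
chronic_lung_diseases,21.8,38.3,36.3,29.6
ocular_complications,4.2,9.7,7.3,6.0
cognitive_impairment,9.3,15.7,12.1,11.1
avascular_necrosis_and_bone_damage,11.9,14.9,20.3,15.9
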
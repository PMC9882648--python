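item_id,item_label,item_kind,round,count_0,count_1,count_2,count_3,count_4,count_5,dont_know,n_respondents
hip_fracture,Hip fracture,health_state_event,1,0,0,0,0,1,8,2,11
hip_fracture_surgery,Surgery for hip fracture,health_state_event,1,0,0,0,0,2,8,1,11
head_injury,Head injury,health_state_event,1,0,0,0,1,1,8,1,11
fall,Fall,health_state_event,1,0,0,0,1,2,7,1,11
long_term_care,"Long-term care housing (e.g., nursing home)",health_state_event,1,0,0,1,0,3,6,1,11
vertebral_fracture,Vertebral fracture,health_state_event,1,0,0,1,1,1,7,1,11
hospitalization,Hospitalization,health_state_event,1,0,0,1,1,1,7,1,11
rehab_hospitalization,Rehabilitation hospitalization,health_state_event,1,0,0,0,0,6,4,1,11
specialized_dementia_care,"Specialized dementia care or memory care in Supportive housing (e.g., retirement home)",health_state_event,1,0,0,1,1,3,5,1,11
post_fall,Post-fall,health_state_event,1,0,0,1,2,1,6,1,11
wrist_fracture,Wrist fracture,health_state_event,1,0,0,0,4,2,4,1,11
ed_visit,Emergency department visit,health_state_event,1,0,1,0,2,2,5,1,11
independent_housing,"Independent housing (e.g., own home)",health_state_event,1,1,0,0,2,4,3,1,11
independent_supported_living,Independent supported living service in Supportive housing,health_state_event,1,0,0,0,4,5,1,1,11
assisted_living,"Assisted living in Supportive housing (e.g., retirement home)",health_state_event,1,0,0,0,4,5,1,1,11
death_due_to_fall,Death due to fall,health_state_event,1,1,2,0,0,1,7,0,11
short_term_supportive_stay,"Short term stay in Supportive housing (e.g., retirement home)",health_state_event,1,0,0,0,6,3,1,1,11
death,Death,health_state_event,1,1,2,0,1,1,6,0,11
fear_of_falling_state,Fear of falling,health_state_event,1,0,0,2,4,1,3,1,11
no_fall_history,No fall history,health_state_event,1,1,2,1,2,1,3,1,11
gait_balance_mobility,"Gait, balance, or mobility difficulties",patient_attribute,1,0,0,0,0,0,10,1,11
history_of_falls,History of falls/previous falls,patient_attribute,1,0,0,0,0,2,8,1,11
impaired_vision,Impaired vision,patient_attribute,1,0,0,0,1,3,6,1,11
older_age,"Age, older age",patient_attribute,1,0,0,0,1,5,5,0,11
dementia_biological,Dementia/cognitive impairment (biological factor),patient_attribute,1,0,0,0,1,4,5,1,11
physical_inactivity,Physical inactivity,patient_attribute,1,0,0,0,0,4,6,1,11
fear_of_falling_attr,Fear of falling,patient_attribute,1,0,0,0,1,5,3,2,11
substance_use,Substance use,patient_attribute,1,0,0,0,2,5,3,1,11
certain_medications,"Use of certain medications (anticonvulsants, tranquilizers, antihypertensives, opioids/narcotics)",patient_attribute,1,0,0,0,0,2,8,1,11
transfer_assistance,Need for transfer assistance,patient_attribute,1,0,0,0,0,6,4,1,11
home_hazards,"Home hazards (e.g., loose carpets, pets, stairs)",patient_attribute,1,0,0,0,1,5,4,1,11
use_of_restraints,Use of restraints,patient_attribute,1,0,0,1,0,5,4,1,11
frailty,"Overall frailty, older age",patient_attribute,1,0,0,0,0,4,6,1,11
parkinsons,Parkinson's disease,patient_attribute,1,0,0,0,0,4,6,1,11
stroke,Stroke,patient_attribute,1,0,0,0,0,4,6,1,11
dementia_condition,Dementia/cognitive impairment (health condition),patient_attribute,1,0,0,0,0,5,5,1,11
multiple_sclerosis,Multiple sclerosis,patient_attribute,1,0,0,0,0,5,4,2,11
osteoporosis,Osteoporosis,patient_attribute,1,0,1,0,0,5,2,3,11
malnutrition_sarcopenia,Malnutrition and related sarcopenia,patient_attribute,1,0,0,0,3,3,2,3,11
sex,Sex,patient_attribute,1,0,0,0,5,1,1,4,11
incontinence,Incontinence,patient_attribute,1,0,0,1,4,4,0,2,11
hurrying_inattention,"Hurrying, not paying attention",patient_attribute,1,0,0,0,4,4,2,1,11
incorrect_assistive_device_use,Incorrect use of assistive devices,patient_attribute,1,0,0,0,4,4,2,1,11
dual_tasking,Dual tasking,patient_attribute,1,0,0,1,3,3,2,2,11
unsupportive_footwear,Wearing unsupportive footwear,patient_attribute,1,0,0,0,5,2,2,2,11
taking_risks,Taking risks,patient_attribute,1,0,0,0,4,6,0,1,11
gender,Gender,patient_attribute,1,0,0,3,2,1,0,5,11
polypharmacy,Polypharmacy,patient_attribute,1,0,0,1,2,1,6,1,11
prolonged_hospital_stay,Prolonged hospital stay,patient_attribute,1,0,0,0,2,5,2,2,11
side_rails,Side rails,patient_attribute,1,0,0,2,2,2,3,2,11
cannot_afford_footwear,Unable to afford supportive footwear,patient_attribute,1,0,0,0,3,5,1,2,11
social_isolation,"No social supports, isolated",patient_attribute,1,0,0,1,2,5,2,1,11
cannot_afford_medications,"Unable to afford certain medications, nutritious food",patient_attribute,1,0,0,0,4,4,1,2,11
unable_to_read,Unable to read,patient_attribute,1,1,1,1,2,2,2,2,11
psychiatric_illness,Psychiatric illness (including depression),patient_attribute,1,0,0,2,2,3,3,1,11
osteoarthritis,Osteoarthritis,patient_attribute,1,0,0,1,3,4,0,3,11
cancer,Cancer,patient_attribute,1,1,0,0,3,4,1,2,11
hemophilia,Hemophilia,patient_attribute,1,1,0,1,1,2,1,5,11
post_fall,Post-fall,health_state_event,2,0,0,0,0,5,3,2,10
wrist_fracture,Wrist fracture,health_state_event,2,0,0,0,1,8,0,1,10
ed_visit,Emergency department visit,health_state_event,2,0,0,0,1,7,2,0,10
independent_housing,"Independent housing (e.g., own home)",health_state_event,2,0,0,1,1,8,0,0,10
death_due_to_fall,Death due to fall,health_state_event,2,0,0,0,1,6,2,1,10
independent_supported_living,Independent supported living service in Supportive housing,health_state_event,2,0,0,0,3,7,0,0,10
assisted_living,"Assisted living in Supportive housing (e.g., retirement home)",health_state_event,2,0,0,0,3,7,0,0,10
short_term_supportive_stay,"Short term stay in Supportive housing (e.g., retirement home)",health_state_event,2,0,0,0,6,4,0,0,10
death,Death,health_state_event,2,0,0,0,4,3,2,1,10
fear_of_falling_state,Fear of falling,health_state_event,2,0,0,0,5,4,0,1,10
no_fall_history,No fall history,health_state_event,2,0,1,3,5,1,0,0,10
ankle_fracture,Ankle fracture,health_state_event,2,0,0,0,4,4,2,0,10
humerus_fracture,Humerus fracture,health_state_event,2,0,0,0,2,6,1,1,10
alternate_level_of_care,Alternate level of care,health_state_event,2,0,0,0,4,3,2,1,10
transitional_care_unit,Transitional care unit,health_state_event,2,0,0,0,4,3,2,1,10
incorrect_assistive_device_use,Incorrect use of assistive devices,patient_attribute,2,0,0,0,1,8,1,0,10
unsupportive_footwear,Wearing unsupportive footwear,patient_attribute,2,0,0,0,0,9,0,1,10
polypharmacy,Polypharmacy,patient_attribute,2,0,0,0,0,7,3,0,10
prolonged_hospital_stay,Prolonged hospital stay,patient_attribute,2,0,0,0,0,9,1,0,10
cannot_afford_footwear,Unable to afford supportive footwear,patient_attribute,2,0,0,0,1,8,0,1,10
social_isolation,"No social supports, isolated",patient_attribute,2,0,0,0,0,10,0,0,10
cannot_afford_medications,"Unable to afford certain medications, nutritious food",patient_attribute,2,0,0,0,1,9,0,0,10
psychiatric_illness,Psychiatric illness (including depression),patient_attribute,2,0,0,0,2,8,0,0,10
malnutrition_sarcopenia,Malnutrition and related sarcopenia,patient_attribute,2,0,0,0,2,6,1,1,10
sex,Sex,patient_attribute,2,0,0,0,7,3,0,0,10
incontinence,Incontinence,patient_attribute,2,0,0,0,6,4,0,0,10
hurrying_inattention,"Hurrying, not paying attention",patient_attribute,2,0,0,0,2,7,0,1,10
dual_tasking,Dual tasking,patient_attribute,2,0,0,0,4,5,0,1,10
taking_risks,Taking risks,patient_attribute,2,0,0,0,2,7,0,1,10
gender,Gender,patient_attribute,2,0,0,2,7,1,0,0,10
side_rails,Side rails,patient_attribute,2,0,0,0,2,7,0,1,10
unable_to_read,Unable to read,patient_attribute,2,0,0,1,5,4,0,0,10
osteoarthritis,Osteoarthritis,patient_attribute,2,0,0,0,6,4,0,0,10
cancer,Cancer,patient_attribute,2,0,0,0,9,0,1,0,10
hemophilia,Hemophilia,patient_attribute,2,0,0,0,9,1,0,0,10
diabetes,Diabetes,patient_attribute,2,0,0,0,4,5,1,0,10
cardiac_disease,Cardiac disease,patient_attribute,2,0,0,1,5,3,1,0,10
hypertension,Hypertension,patient_attribute,2,0,0,0,6,4,0,0,10
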
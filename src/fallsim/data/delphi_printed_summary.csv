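item_id,item_kind,round,printed_average,printed_block
hip_fracture,health_state_event,1,4.89,inclusion
hip_fracture_surgery,health_state_event,1,4.80,inclusion
head_injury,health_state_event,1,4.70,inclusion
fall,health_state_event,1,4.60,inclusion
long_term_care,health_state_event,1,4.40,inclusion
vertebral_fracture,health_state_event,1,4.40,inclusion
hospitalization,health_state_event,1,4.40,inclusion
rehab_hospitalization,health_state_event,1,4.40,inclusion
specialized_dementia_care,health_state_event,1,4.20,inclusion
post_fall,health_state_event,1,4.20,non_consensus
wrist_fracture,health_state_event,1,4.00,non_consensus
ed_visit,health_state_event,1,4.00,non_consensus
independent_housing,health_state_event,1,3.70,non_consensus
independent_supported_living,health_state_event,1,3.70,non_consensus
assisted_living,health_state_event,1,3.70,non_consensus
death_due_to_fall,health_state_event,1,3.73,non_consensus
short_term_supportive_stay,health_state_event,1,3.50,non_consensus
death,health_state_event,1,3.55,non_consensus
fear_of_falling_state,health_state_event,1,3.50,non_consensus
no_fall_history,health_state_event,1,2.90,non_consensus
gait_balance_mobility,patient_attribute,1,5.00,inclusion
history_of_falls,patient_attribute,1,4.80,inclusion
impaired_vision,patient_attribute,1,4.50,inclusion
older_age,patient_attribute,1,4.36,inclusion
dementia_biological,patient_attribute,1,4.40,inclusion
physical_inactivity,patient_attribute,1,4.60,inclusion
fear_of_falling_attr,patient_attribute,1,4.22,inclusion
substance_use,patient_attribute,1,4.10,inclusion
certain_medications,patient_attribute,1,4.80,inclusion
transfer_assistance,patient_attribute,1,4.40,inclusion
home_hazards,patient_attribute,1,4.30,inclusion
use_of_restraints,patient_attribute,1,4.20,inclusion
frailty,patient_attribute,1,4.60,inclusion
parkinsons,patient_attribute,1,4.60,inclusion
stroke,patient_attribute,1,4.60,inclusion
dementia_condition,patient_attribute,1,4.50,inclusion
multiple_sclerosis,patient_attribute,1,4.44,inclusion
osteoporosis,patient_attribute,1,3.88,inclusion
malnutrition_sarcopenia,patient_attribute,1,3.88,non_consensus
sex,patient_attribute,1,3.43,non_consensus
incontinence,patient_attribute,1,3.33,non_consensus
hurrying_inattention,patient_attribute,1,3.80,non_consensus
incorrect_assistive_device_use,patient_attribute,1,3.80,non_consensus
dual_tasking,patient_attribute,1,3.67,non_consensus
unsupportive_footwear,patient_attribute,1,3.67,non_consensus
taking_risks,patient_attribute,1,3.60,non_consensus
gender,patient_attribute,1,2.67,non_consensus
polypharmacy,patient_attribute,1,4.20,non_consensus
prolonged_hospital_stay,patient_attribute,1,4.00,non_consensus
side_rails,patient_attribute,1,3.67,non_consensus
cannot_afford_footwear,patient_attribute,1,3.78,non_consensus
social_isolation,patient_attribute,1,3.80,non_consensus
cannot_afford_medications,patient_attribute,1,3.67,non_consensus
unable_to_read,patient_attribute,1,3.00,non_consensus
psychiatric_illness,patient_attribute,1,3.70,non_consensus
osteoarthritis,patient_attribute,1,3.38,non_consensus
cancer,patient_attribute,1,3.33,non_consensus
hemophilia,patient_attribute,1,3.00,non_consensus
post_fall,health_state_event,2,4.38,inclusion
wrist_fracture,health_state_event,2,3.89,inclusion
ed_visit,health_state_event,2,4.10,inclusion
independent_housing,health_state_event,2,3.70,inclusion
death_due_to_fall,health_state_event,2,4.11,inclusion
independent_supported_living,health_state_event,2,3.70,non_consensus
assisted_living,health_state_event,2,3.70,non_consensus
short_term_supportive_stay,health_state_event,2,3.40,non_consensus
death,health_state_event,2,3.78,non_consensus
fear_of_falling_state,health_state_event,2,3.44,non_consensus
no_fall_history,health_state_event,2,2.60,non_consensus
ankle_fracture,health_state_event,2,3.80,non_consensus
humerus_fracture,health_state_event,2,3.89,non_consensus
alternate_level_of_care,health_state_event,2,3.78,non_consensus
transitional_care_unit,health_state_event,2,3.78,non_consensus
incorrect_assistive_device_use,patient_attribute,2,4.00,inclusion
unsupportive_footwear,patient_attribute,2,4.00,inclusion
polypharmacy,patient_attribute,2,4.30,inclusion
prolonged_hospital_stay,patient_attribute,2,4.10,inclusion
cannot_afford_footwear,patient_attribute,2,3.89,inclusion
social_isolation,patient_attribute,2,4.00,inclusion
cannot_afford_medications,patient_attribute,2,3.90,inclusion
psychiatric_illness,patient_attribute,2,3.80,inclusion
malnutrition_sarcopenia,patient_attribute,2,3.89,non_consensus
sex,patient_attribute,2,3.30,non_consensus
incontinence,patient_attribute,2,3.40,non_consensus
hurrying_inattention,patient_attribute,2,3.78,non_consensus
dual_tasking,patient_attribute,2,3.56,non_consensus
taking_risks,patient_attribute,2,3.78,non_consensus
gender,patient_attribute,2,2.90,non_consensus
side_rails,patient_attribute,2,3.78,non_consensus
unable_to_read,patient_attribute,2,3.30,non_consensus
osteoarthritis,patient_attribute,2,3.40,non_consensus
cancer,patient_attribute,2,3.20,non_consensus
hemophilia,patient_attribute,2,3.10,non_consensus
diabetes,patient_attribute,2,3.70,non_consensus
cardiac_disease,patient_attribute,2,3.40,non_consensus
hypertension,patient_attribute,2,3.40,non_consensus
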
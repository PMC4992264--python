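# Mapping from extraction-condition names to comorbidity-index components.
# Columns: condition	index	component	weight
# CCI weights follow the original Charlson enumeration (1/2/3/6); ECI
# components each count 1. Edit or extend this table for site-specific
# condition vocabularies.
condition	index	component	weight
myocardial_infarction	cci	myocardial_infarction	1
congestive_heart_failure	cci	congestive_heart_failure	1
peripheral_vascular_disease	cci	peripheral_vascular_disease	1
dementia	cci	dementia	1
copd	cci	chronic_pulmonary_disease	1
peptic_ulcer_disease	cci	peptic_ulcer_disease	1
mild_liver_disease	cci	mild_liver_disease	1
diabetes	cci	diabetes	1
diabetes_with_complications	cci	diabetes_with_complications	2
paralysis	cci	hemiplegia	2
lymphoma	cci	lymphoma	2
any_malignancy	cci	any_malignancy	2
moderate_severe_liver_disease	cci	moderate_severe_liver_disease	3
metastatic_solid_tumor	cci	metastatic_solid_tumor	6
aids	cci	aids	6
hypertension	eci	hypertension	1
diabetes	eci	diabetes_uncomplicated	1
diabetes_with_complications	eci	diabetes_complicated	1
copd	eci	chronic_pulmonary_disease	1
depression	eci	depression	1
aids	eci	aids_hiv	1
metastatic_solid_tumor	eci	metastatic_cancer	1
any_malignancy	eci	solid_tumor_without_metastasis	1
peptic_ulcer_disease	eci	peptic_ulcer_disease	1
fluid_electrolyte_disorders	eci	fluid_electrolyte_disorders	1
valvular_disease	eci	valvular_disease	1
pulmonary_circulation_disorders	eci	pulmonary_circulation_disorders	1
paralysis	eci	paralysis	1
lymphoma	eci	lymphoma	1
coagulopathy	eci	coagulopathy	1
psychoses	eci	psychoses	1
congestive_heart_failure	eci	congestive_heart_failure	1
peripheral_vascular_disease	eci	peripheral_vascular_disorders	1
weight_loss	eci	weight_loss	1
mild_liver_disease	eci	liver_disease	1
moderate_severe_liver_disease	eci	liver_disease	1
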
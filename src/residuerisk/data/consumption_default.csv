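population,category,intake_mean_kg_day,body_weight_kg,cv
children_2_7,vegetable,0.19,19,
children_2_7,fruit,0.12,19,
children_2_7,cereal,0.22,19,
children_2_7,potato,0.035,19,
adolescent_male,vegetable,0.42,50,
adolescent_male,fruit,0.26,50,
adolescent_male,cereal,0.50,50,
adolescent_male,potato,0.080,50,
adolescent_female,vegetable,0.38,46,
adolescent_female,fruit,0.24,46,
adolescent_female,cereal,0.44,46,
adolescent_female,potato,0.070,46,
adult_male,vegetable,0.44,63,
adult_male,fruit,0.28,63,
adult_male,cereal,0.45,63,
adult_male,potato,0.085,63,
adult_female,vegetable,0.38,56,
adult_female,fruit,0.26,56,
adult_female,cereal,0.38,56,
adult_female,potato,0.070,56,
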
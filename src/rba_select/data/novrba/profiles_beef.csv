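component_id,food_id,domain,concentration,unit,prevalence_fraction,sample_detection_fraction,processing_effect,evidence_level,processing_effect_class,fbdg_scope,fortification_scope,intake_contribution_fraction,composition_difference_class,bioavailability_reduction,prevalence_class,process_effect_class,daly_per_1000_cases,above_lod_loq,genotoxic_carcinogen,exceeds_hbgv,moe_below_10000,exposure_share_of_diet,sev_high_incidence,sev_fatal,sev_lifelong_disability,sev_high_disability
Carbohydrates,beef,nutrition,76.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Fiber (insoluble),beef,nutrition,39.9,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Fiber (soluble),beef,nutrition,70.4,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Aluminum,beef,nutrition,7.5,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Calcium,beef,nutrition,45.9,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Chloride,beef,nutrition,30.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Chromium,beef,nutrition,73.8,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Copper,beef,nutrition,35.2,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Iodine,beef,nutrition,10.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Iron,beef,nutrition,22.1,mg/100g,,1.0,,convincing,preserved_or_concentrated,all_countries,some_countries,0.9,,mild_or_none,,,,,,,,,,,,
Magnesium,beef,nutrition,34.2,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Manganese,beef,nutrition,57.6,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Potassium,beef,nutrition,21.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Selenium,beef,nutrition,62.4,mg/100g,,1.0,,convincing,preserved_or_concentrated,all_countries,none,0.5,,moderate,,,,,,,,,,,,
Sodium,beef,nutrition,51.0,mg/100g,,1.0,,convincing,preserved_or_concentrated,all_countries,some_countries,0.9,,mild_or_none,,,,,,,,,,,,
Sulfur,beef,nutrition,11.4,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Zinc,beef,nutrition,18.0,mg/100g,,1.0,,convincing,preserved_or_concentrated,all_countries,some_countries,0.9,,mild_or_none,,,,,,,,,,,,
Niacin,beef,nutrition,81.9,mg/100g,,1.0,,convincing,preserved_or_concentrated,all_countries,none,0.5,,moderate,,,,,,,,,,,,
Thiamin,beef,nutrition,58.5,mg/100g,,1.0,,convincing,preserved_or_concentrated,all_countries,none,0.5,,moderate,,,,,,,,,,,,
Vitamin B12 (cyanocobalamin),beef,nutrition,66.5,mg/100g,,1.0,,convincing,preserved_or_concentrated,all_countries,none,0.5,,moderate,,,,,,,,,,,,
Vitamin D3,beef,nutrition,83.6,mg/100g,,1.0,,convincing,preserved_or_concentrated,all_countries,none,0.5,,moderate,,,,,,,,,,,,
Total SFA,beef,nutrition,19.8,mg/100g,,1.0,,convincing,preserved_or_concentrated,all_countries,none,0.5,,moderate,,,,,,,,,,,,
Cholesterol,beef,nutrition,65.6,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Alanine,beef,nutrition,37.8,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Cystine/cysteine,beef,nutrition,30.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Histidine,beef,nutrition,28.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Lysine,beef,nutrition,66.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Methionine,beef,nutrition,9.5,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Phenylalanine,beef,nutrition,59.2,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Tryptophan,beef,nutrition,10.8,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Bacillus cereus,beef,microbiology,,,,,,convincing,,,,,,,low,reduces_or_eliminates,3,,,,,,,,,
Campylobacter spp.,beef,microbiology,,,,,,convincing,,,,,,,moderate,neutral,40,,,,,,,,,
Clostridium perfringens,beef,microbiology,,,,,,convincing,,,,,,,high,neutral,5,,,,,,,,,
Cronobacter sakazakii,beef,microbiology,,,,,,convincing,,,,,,,low,reduces_or_eliminates,3,,,,,,,,,
EHEC,beef,microbiology,,,,,,convincing,,,,,,,low,reduces_or_eliminates,3,,,,,,,,,
Listeria monocytogenes,beef,microbiology,,,,,,convincing,,,,,,,low,neutral,900,,,,,,,,,
Salmonella spp.,beef,microbiology,,,,,,convincing,,,,,,,moderate,neutral,50,,,,,,,,,
Staphylococcus aureus (enterotoxin),beef,microbiology,,,,,,convincing,,,,,,,moderate,neutral,5,,,,,,,,,
Yersinia enterocolitica,beef,microbiology,,,,,,convincing,,,,,,,low,reduces_or_eliminates,3,,,,,,,,,
Hepatitis E virus,beef,microbiology,,,,,,convincing,,,,,,,low,reduces_or_eliminates,3,,,,,,,,,
Norovirus,beef,microbiology,,,,,,convincing,,,,,,,low,reduces_or_eliminates,3,,,,,,,,,
Rotavirus,beef,microbiology,,,,,,convincing,,,,,,,low,reduces_or_eliminates,3,,,,,,,,,
Cryptosporidium spp.,beef,microbiology,,,,,,convincing,,,,,,,low,reduces_or_eliminates,3,,,,,,,,,
Toxoplasma gondii,beef,microbiology,,,,,,convincing,,,,,,,low,neutral,300,,,,,,,,,
Total PCB,beef,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
Dioxins and dl-PCBs,beef,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
Organochlorine compounds,beef,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
Methylmercury,beef,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
Cadmium,beef,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
Lead,beef,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
Inorganic arsenic,beef,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
Aluminum (contaminant),beef,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
Nickel,beef,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
Chromium (contaminant),beef,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
PAH,beef,toxicology,,,,,,convincing,,,,,,,,,,true,true,,true,0.3,false,true,true,false
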
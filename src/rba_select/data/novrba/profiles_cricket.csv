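component_id,food_id,domain,concentration,unit,prevalence_fraction,sample_detection_fraction,processing_effect,evidence_level,processing_effect_class,fbdg_scope,fortification_scope,intake_contribution_fraction,composition_difference_class,bioavailability_reduction,prevalence_class,process_effect_class,daly_per_1000_cases,above_lod_loq,genotoxic_carcinogen,exceeds_hbgv,moe_below_10000,exposure_share_of_diet,sev_high_incidence,sev_fatal,sev_lifelong_disability,sev_high_disability
Carbohydrates,cricket,nutrition,40.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Fiber (insoluble),cricket,nutrition,19.0,mg/100g,,1.0,,convincing,preserved_or_concentrated,all_countries,none,0.5,,moderate,,,,,,,,,,,,
Fiber (soluble),cricket,nutrition,44.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Aluminum,cricket,nutrition,5.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Calcium,cricket,nutrition,27.0,mg/100g,,1.0,,convincing,preserved_or_concentrated,all_countries,some_countries,0.9,,mild_or_none,,,,,,,,,,,,
Chloride,cricket,nutrition,15.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Chromium,cricket,nutrition,41.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Copper,cricket,nutrition,22.0,mg/100g,,1.0,,convincing,preserved_or_concentrated,all_countries,none,0.5,,moderate,,,,,,,,,,,,
Iodine,cricket,nutrition,5.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Iron,cricket,nutrition,13.0,mg/100g,,1.0,,convincing,preserved_or_concentrated,all_countries,some_countries,0.9,,mild_or_none,,,,,,,,,,,,
Magnesium,cricket,nutrition,19.0,mg/100g,,1.0,,convincing,preserved_or_concentrated,all_countries,none,0.5,,moderate,,,,,,,,,,,,
Manganese,cricket,nutrition,36.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Potassium,cricket,nutrition,10.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Selenium,cricket,nutrition,39.0,mg/100g,,1.0,,convincing,preserved_or_concentrated,all_countries,none,0.5,,moderate,,,,,,,,,,,,
Sodium,cricket,nutrition,30.0,mg/100g,,1.0,,convincing,preserved_or_concentrated,all_countries,some_countries,0.9,,mild_or_none,,,,,,,,,,,,
Sulfur,cricket,nutrition,6.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Zinc,cricket,nutrition,9.0,mg/100g,,1.0,,convincing,preserved_or_concentrated,all_countries,some_countries,0.9,,mild_or_none,,,,,,,,,,,,
Niacin,cricket,nutrition,39.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Thiamin,cricket,nutrition,39.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Vitamin B12 (cyanocobalamin),cricket,nutrition,35.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Vitamin D3,cricket,nutrition,44.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Total SFA,cricket,nutrition,11.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Folate,cricket,nutrition,8.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Pantothenic acid,cricket,nutrition,27.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Retinol,cricket,nutrition,18.0,mg/100g,,1.0,,limited,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Riboflavin,cricket,nutrition,41.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Pyridoxine,cricket,nutrition,32.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Vitamin C,cricket,nutrition,32.0,mg/100g,,1.0,,contradictory,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Vitamin E,cricket,nutrition,34.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Total MUFAs,cricket,nutrition,5.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Total PUFAs,cricket,nutrition,8.0,mg/100g,,1.0,,convincing,moderate_change,some_countries,none,0.5,,moderate,,,,,,,,,,,,
Total n-3 fatty acids,cricket,nutrition,11.0,mg/100g,,1.0,,convincing,preserved_or_concentrated,all_countries,none,0.5,,moderate,,,,,,,,,,,,
Total n-6 fatty acids,cricket,nutrition,14.0,mg/100g,,1.0,,convincing,preserved_or_concentrated,all_countries,none,0.5,,moderate,,,,,,,,,,,,
Bacillus cereus,cricket,microbiology,,,,,,convincing,,,,,,,high,neutral,4,,,,,,,,,
Campylobacter spp.,cricket,microbiology,,,,,,convincing,,,,,,,low,reduces_or_eliminates,3,,,,,,,,,
Clostridium botulinum,cricket,microbiology,,,,,,convincing,,,,,,,low,neutral,800,,,,,,,,,
Clostridium perfringens,cricket,microbiology,,,,,,convincing,,,,,,,high,neutral,5,,,,,,,,,
Cronobacter sakazakii,cricket,microbiology,,,,,,convincing,,,,,,,moderate,neutral,150,,,,,,,,,
EHEC,cricket,microbiology,,,,,,convincing,,,,,,,low,reduces_or_eliminates,3,,,,,,,,,
Listeria monocytogenes,cricket,microbiology,,,,,,convincing,,,,,,,low,neutral,900,,,,,,,,,
Salmonella spp.,cricket,microbiology,,,,,,convincing,,,,,,,moderate,neutral,50,,,,,,,,,
Staphylococcus aureus (enterotoxin),cricket,microbiology,,,,,,convincing,,,,,,,moderate,neutral,5,,,,,,,,,
Vibrio spp.,cricket,microbiology,,,,,,convincing,,,,,,,low,reduces_or_eliminates,3,,,,,,,,,
Yersinia enterocolitica,cricket,microbiology,,,,,,convincing,,,,,,,low,reduces_or_eliminates,3,,,,,,,,,
Hepatitis A virus,cricket,microbiology,,,,,,convincing,,,,,,,low,reduces_or_eliminates,3,,,,,,,,,
Norovirus,cricket,microbiology,,,,,,convincing,,,,,,,low,reduces_or_eliminates,3,,,,,,,,,
Histamine,cricket,microbiology,,,,,,convincing,,,,,,,low,reduces_or_eliminates,3,,,,,,,,,
Total PCB,cricket,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
Phosphorous flame retardants,cricket,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
Oxychlordane,cricket,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
PBDE,cricket,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
Mercury,cricket,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
Cadmium,cricket,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
Lead,cricket,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
Inorganic arsenic,cricket,toxicology,,,,,,convincing,,,,,,,,,,true,true,,true,0.3,false,true,true,false
Aluminum (contaminant),cricket,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
Nickel,cricket,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
Chromium (contaminant),cricket,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
Pesticides (10 compounds),cricket,toxicology,,,,,,convincing,,,,,,,,,,false,false,,,0.05,false,false,false,false
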
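component_id,food_id,has_dose_response,has_incidence,has_source_attribution,has_intake_data,has_composition_or_contamination,has_daly_per_case
Calcium,cricket,true,true,,true,true,true
Calcium,beef,true,true,,true,true,true
Copper,cricket,false,true,,true,true,true
Copper,beef,false,true,,true,true,true
Fiber (insoluble),cricket,true,true,,true,true,true
Fiber (insoluble),beef,true,true,,true,true,true
Iron,cricket,true,true,,true,true,true
Iron,beef,true,true,,true,true,true
Magnesium,cricket,true,true,,true,true,true
Magnesium,beef,true,true,,true,true,true
Niacin,cricket,false,true,,true,true,true
Niacin,beef,false,true,,true,true,true
Selenium,cricket,false,true,,true,true,true
Selenium,beef,false,true,,true,true,true
Sodium,cricket,true,true,,true,true,true
Sodium,beef,true,true,,true,true,true
Thiamin,cricket,false,true,,true,true,true
Thiamin,beef,false,true,,true,true,true
Total SFA,cricket,false,true,,true,true,true
Total SFA,beef,false,true,,true,true,true
Total n-3 fatty acids,cricket,false,true,,true,true,true
Total n-3 fatty acids,beef,false,true,,true,true,true
Total n-6 fatty acids,cricket,false,true,,true,true,true
Total n-6 fatty acids,beef,false,true,,true,true,true
Vitamin B12 (cyanocobalamin),cricket,true,true,,true,true,true
Vitamin B12 (cyanocobalamin),beef,true,true,,true,true,true
Vitamin D3,cricket,false,true,,true,true,true
Vitamin D3,beef,false,true,,true,true,true
Zinc,cricket,true,true,,true,true,true
Zinc,beef,true,true,,true,true,true
Bacillus cereus,cricket,true,true,true,true,true,true
Clostridium botulinum,cricket,true,false,true,true,true,true
Clostridium perfringens,cricket,true,true,true,true,true,true
Cronobacter sakazakii,cricket,true,true,true,true,true,true
Listeria monocytogenes,cricket,true,true,true,true,true,true
Salmonella spp.,cricket,true,true,true,true,true,true
Staphylococcus aureus (enterotoxin),cricket,true,true,true,true,true,false
Campylobacter spp.,beef,true,true,false,true,true,true
Clostridium perfringens,beef,true,true,true,true,true,true
Listeria monocytogenes,beef,true,true,false,true,true,true
Salmonella spp.,beef,true,true,true,true,true,true
Staphylococcus aureus (enterotoxin),beef,true,true,true,true,true,false
Toxoplasma gondii,beef,true,true,true,true,true,true
Inorganic arsenic,cricket,false,true,,true,true,true
PAH,beef,true,true,,true,true,false
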
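component_id,outcome_name,direction
Calcium,Colorectal cancer,beneficial
Fiber (insoluble),Coronary heart disease,beneficial
Fiber (insoluble),Colorectal cancer,beneficial
Iron,Iron-deficiency anemia,beneficial
Magnesium,Stroke,beneficial
Sodium,Cardiovascular disease,adverse
Sodium,Iodine status support,beneficial
Vitamin B12 (cyanocobalamin),Megaloblastic anemia,beneficial
Zinc,Impaired immune function,beneficial
Bacillus cereus,Toxin-mediated gastroenteritis,adverse
Clostridium perfringens,Gastroenteritis,adverse
Cronobacter sakazakii,Invasive infection,adverse
Listeria monocytogenes,Listeriosis,adverse
Salmonella spp.,Salmonellosis,adverse
Toxoplasma gondii,Toxoplasmosis,adverse
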
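component,max_points,direction,max_standard,min_standard,units
total_fruit,5,adequacy,0.8,,cup_equiv_per_1000kcal
whole_fruit,5,adequacy,0.4,,cup_equiv_per_1000kcal
total_veg,5,adequacy,1.1,,cup_equiv_per_1000kcal
dgo_veg_legumes,5,adequacy,0.4,,cup_equiv_per_1000kcal
total_grains,5,adequacy,3.0,,oz_equiv_per_1000kcal
whole_grains,5,adequacy,1.5,,oz_equiv_per_1000kcal
milk,10,adequacy,1.3,,cup_equiv_per_1000kcal
meat_beans,10,adequacy,2.5,,oz_equiv_per_1000kcal
oils,10,adequacy,12.0,,g_per_1000kcal
sat_fat,10,moderation,7.0,15.0,pct_energy
sodium,10,moderation,0.7,2.0,g_per_1000kcal
sofaas,20,moderation,20.0,50.0,pct_energy
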
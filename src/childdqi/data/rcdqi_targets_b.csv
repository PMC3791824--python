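component,age,target,units
total_grains,2,3,oz_equiv_per_day
total_grains,3,3,oz_equiv_per_day
total_grains,4,4,oz_equiv_per_day
total_grains,5,4,oz_equiv_per_day
total_grains,6,4,oz_equiv_per_day
total_grains,7,4,oz_equiv_per_day
total_grains,8,4,oz_equiv_per_day
total_grains,9,6,oz_equiv_per_day
total_grains,10,6,oz_equiv_per_day
total_grains,11,6,oz_equiv_per_day
total_grains,12,6,oz_equiv_per_day
total_grains,13,6,oz_equiv_per_day
total_grains,14,7,oz_equiv_per_day
total_grains,15,7,oz_equiv_per_day
total_grains,16,7,oz_equiv_per_day
total_grains,17,7,oz_equiv_per_day
total_grains,18,7,oz_equiv_per_day
whole_grains,2,1.5,oz_equiv_per_day
whole_grains,3,1.5,oz_equiv_per_day
whole_grains,4,2,oz_equiv_per_day
whole_grains,5,2,oz_equiv_per_day
whole_grains,6,2,oz_equiv_per_day
whole_grains,7,2,oz_equiv_per_day
whole_grains,8,2,oz_equiv_per_day
whole_grains,9,3,oz_equiv_per_day
whole_grains,10,3,oz_equiv_per_day
whole_grains,11,3,oz_equiv_per_day
whole_grains,12,3,oz_equiv_per_day
whole_grains,13,3,oz_equiv_per_day
whole_grains,14,3.5,oz_equiv_per_day
whole_grains,15,3.5,oz_equiv_per_day
whole_grains,16,3.5,oz_equiv_per_day
whole_grains,17,3.5,oz_equiv_per_day
whole_grains,18,3.5,oz_equiv_per_day
fruit,2,1.5,cup_equiv_per_day
fruit,3,1.5,cup_equiv_per_day
fruit,4,1.5,cup_equiv_per_day
fruit,5,1.5,cup_equiv_per_day
fruit,6,1.5,cup_equiv_per_day
fruit,7,1.5,cup_equiv_per_day
fruit,8,1.5,cup_equiv_per_day
fruit,9,2,cup_equiv_per_day
fruit,10,2,cup_equiv_per_day
fruit,11,2,cup_equiv_per_day
fruit,12,2,cup_equiv_per_day
fruit,13,2,cup_equiv_per_day
fruit,14,2,cup_equiv_per_day
fruit,15,2,cup_equiv_per_day
fruit,16,2,cup_equiv_per_day
fruit,17,2,cup_equiv_per_day
fruit,18,2,cup_equiv_per_day
vegetable,2,1,cup_equiv_per_day
vegetable,3,1,cup_equiv_per_day
vegetable,4,2,cup_equiv_per_day
vegetable,5,2,cup_equiv_per_day
vegetable,6,2,cup_equiv_per_day
vegetable,7,2,cup_equiv_per_day
vegetable,8,2,cup_equiv_per_day
vegetable,9,3,cup_equiv_per_day
vegetable,10,3,cup_equiv_per_day
vegetable,11,3,cup_equiv_per_day
vegetable,12,3,cup_equiv_per_day
vegetable,13,3,cup_equiv_per_day
vegetable,14,4,cup_equiv_per_day
vegetable,15,4,cup_equiv_per_day
vegetable,16,4,cup_equiv_per_day
vegetable,17,4,cup_equiv_per_day
vegetable,18,4,cup_equiv_per_day
dairy,2,2,cup_equiv_per_day
dairy,3,2,cup_equiv_per_day
dairy,4,2,cup_equiv_per_day
dairy,5,2,cup_equiv_per_day
dairy,6,2,cup_equiv_per_day
dairy,7,2,cup_equiv_per_day
dairy,8,2,cup_equiv_per_day
dairy,9,3,cup_equiv_per_day
dairy,10,3,cup_equiv_per_day
dairy,11,3,cup_equiv_per_day
dairy,12,3,cup_equiv_per_day
dairy,13,3,cup_equiv_per_day
dairy,14,3,cup_equiv_per_day
dairy,15,3,cup_equiv_per_day
dairy,16,3,cup_equiv_per_day
dairy,17,3,cup_equiv_per_day
dairy,18,3,cup_equiv_per_day
juice_limit,2,6,fl_oz_per_day
juice_limit,3,6,fl_oz_per_day
juice_limit,4,6,fl_oz_per_day
juice_limit,5,6,fl_oz_per_day
juice_limit,6,6,fl_oz_per_day
juice_limit,7,12,fl_oz_per_day
juice_limit,8,12,fl_oz_per_day
juice_limit,9,12,fl_oz_per_day
juice_limit,10,12,fl_oz_per_day
juice_limit,11,12,fl_oz_per_day
juice_limit,12,12,fl_oz_per_day
juice_limit,13,12,fl_oz_per_day
juice_limit,14,12,fl_oz_per_day
juice_limit,15,12,fl_oz_per_day
juice_limit,16,12,fl_oz_per_day
juice_limit,17,12,fl_oz_per_day
juice_limit,18,12,fl_oz_per_day
eer,2,1072,kcal_per_day
eer,3,1080,kcal_per_day
eer,4,1133,kcal_per_day
eer,5,1189,kcal_per_day
eer,6,1247,kcal_per_day
eer,7,1298,kcal_per_day
eer,8,1360,kcal_per_day
eer,9,1415,kcal_per_day
eer,10,1470,kcal_per_day
eer,11,1538,kcal_per_day
eer,12,1617,kcal_per_day
eer,13,1684,kcal_per_day
eer,14,1718,kcal_per_day
eer,15,1731,kcal_per_day
eer,16,1729,kcal_per_day
eer,17,1710,kcal_per_day
eer,18,1690,kcal_per_day
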
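component,age,target,units
total_grains,2,3,oz_equiv_per_day
total_grains,3,3,oz_equiv_per_day
total_grains,4,5,oz_equiv_per_day
total_grains,5,5,oz_equiv_per_day
total_grains,6,5,oz_equiv_per_day
total_grains,7,5,oz_equiv_per_day
total_grains,8,5,oz_equiv_per_day
total_grains,9,7,oz_equiv_per_day
total_grains,10,7,oz_equiv_per_day
total_grains,11,7,oz_equiv_per_day
total_grains,12,7,oz_equiv_per_day
total_grains,13,7,oz_equiv_per_day
total_grains,14,9,oz_equiv_per_day
total_grains,15,9,oz_equiv_per_day
total_grains,16,9,oz_equiv_per_day
total_grains,17,9,oz_equiv_per_day
total_grains,18,9,oz_equiv_per_day
whole_grains,2,1.5,oz_equiv_per_day
whole_grains,3,1.5,oz_equiv_per_day
whole_grains,4,2.5,oz_equiv_per_day
whole_grains,5,2.5,oz_equiv_per_day
whole_grains,6,2.5,oz_equiv_per_day
whole_grains,7,2.5,oz_equiv_per_day
whole_grains,8,2.5,oz_equiv_per_day
whole_grains,9,3.5,oz_equiv_per_day
whole_grains,10,3.5,oz_equiv_per_day
whole_grains,11,3.5,oz_equiv_per_day
whole_grains,12,3.5,oz_equiv_per_day
whole_grains,13,3.5,oz_equiv_per_day
whole_grains,14,4.5,oz_equiv_per_day
whole_grains,15,4.5,oz_equiv_per_day
whole_grains,16,4.5,oz_equiv_per_day
whole_grains,17,4.5,oz_equiv_per_day
whole_grains,18,4.5,oz_equiv_per_day
fruit,2,1.5,cup_equiv_per_day
fruit,3,1.5,cup_equiv_per_day
fruit,4,2,cup_equiv_per_day
fruit,5,2,cup_equiv_per_day
fruit,6,2,cup_equiv_per_day
fruit,7,2,cup_equiv_per_day
fruit,8,2,cup_equiv_per_day
fruit,9,2,cup_equiv_per_day
fruit,10,2,cup_equiv_per_day
fruit,11,2,cup_equiv_per_day
fruit,12,2,cup_equiv_per_day
fruit,13,2,cup_equiv_per_day
fruit,14,3,cup_equiv_per_day
fruit,15,3,cup_equiv_per_day
fruit,16,3,cup_equiv_per_day
fruit,17,3,cup_equiv_per_day
fruit,18,3,cup_equiv_per_day
vegetable,2,1,cup_equiv_per_day
vegetable,3,1,cup_equiv_per_day
vegetable,4,2,cup_equiv_per_day
vegetable,5,2,cup_equiv_per_day
vegetable,6,2,cup_equiv_per_day
vegetable,7,2,cup_equiv_per_day
vegetable,8,2,cup_equiv_per_day
vegetable,9,4,cup_equiv_per_day
vegetable,10,4,cup_equiv_per_day
vegetable,11,4,cup_equiv_per_day
vegetable,12,4,cup_equiv_per_day
vegetable,13,4,cup_equiv_per_day
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
eer,2,1120,kcal_per_day
eer,3,1162,kcal_per_day
eer,4,1215,kcal_per_day
eer,5,1275,kcal_per_day
eer,6,1328,kcal_per_day
eer,7,1393,kcal_per_day
eer,8,1453,kcal_per_day
eer,9,1530,kcal_per_day
eer,10,1601,kcal_per_day
eer,11,1691,kcal_per_day
eer,12,1798,kcal_per_day
eer,13,1935,kcal_per_day
eer,14,2090,kcal_per_day
eer,15,2223,kcal_per_day
eer,16,2320,kcal_per_day
eer,17,2366,kcal_per_day
eer,18,2383,kcal_per_day
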
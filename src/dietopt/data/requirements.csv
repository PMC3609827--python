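nutrient_id,unit,min,max,sd
energy,kJ,11450.0,,184.4
protein,g,52.0,,5.0
fiber,g,30.0,,2.5
pufa,g,13.1,,1.3
sat_fat,g,,30.0,0.0
sodium,mg,,2300.0,0.0
potassium,mg,3800.0,,385.0
calcium,mg,840.0,,80.0
iron,mg,8.0,,0.8
zinc,mg,12.0,,1.0
selenium,ug,60.0,,6.0
vitamin_a,ug RE,625.0,3000.0,123.0
thiamine,mg,1.0,,0.1
vitamin_c,mg,30.0,,6.6
vitamin_e,mg,10.0,,1.0
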
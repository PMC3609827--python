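id: NZ_S
description: >
  Familiar "sausages and potatoes" evening meal with two other vegetables
  and an ice-cream-and-canned-fruit dessert, plus the standard breakfast
  and lunch; everything else optimized for cost.
objective: min_cost
per_food_min:
  sausages: 96
  potatoes: 426
  ice_cream: 66
  canned_peaches: 147
  oats: 39
  skim_milk_powder: 25
  sugar: 7
  bread_wholemeal: 112
  cheese: 24
  peanut_butter: 25
  margarine: 20
  apple: 130
  salt: 1.5
category_constraints:
  - name: two_other_vegetables
    any_of: [vegetable]
    none_of: [starchy_root]
    total_min: 200   # two vegetables at >=100 g each, compiled as grams
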
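id: NZ_T
description: >
  Familiar "tuna pasta bake" evening meal (canned tuna, pasta, canned
  tomatoes, another vegetable) plus the standard breakfast and lunch;
  everything else optimized for cost.
objective: min_cost
per_food_min:
  canned_tuna: 124
  pasta: 118
  canned_tomatoes: 120
  oats: 39
  skim_milk_powder: 25
  sugar: 7
  bread_wholemeal: 112
  cheese: 24
  peanut_butter: 25
  margarine: 20
  apple: 130
  salt: 3
category_constraints:
  - name: other_vegetable
    any_of: [vegetable]
    none_of: [starchy_root]
    exclude_ids: [canned_tomatoes]
    total_min: 100
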
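id: MED
description: >
  Least-cost Mediterranean-style pattern: >=549 g non-starchy vegetables,
  >=363 g fruit and nuts, >=24 g fish and seafood, >=56 g olive oil, salt
  for cooking. Other traditional components (legumes, cereals, dairy) are
  left to the optimizer.
objective: min_cost
per_food_min:
  olive_oil: 56
  salt: 3
category_constraints:
  - name: vegetables_med
    any_of: [vegetable]
    none_of: [starchy_root, juice]
    total_min: 549
  - name: fruit_and_nuts
    any_of: [fruit, nut]
    total_min: 363
  - name: fish_seafood
    any_of: [fish]
    total_min: 24
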
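id: MED_G
description: >
  Mediterranean-style pattern minimizing GHG emissions under NZ$9/day;
  the fish requirement is dropped.
objective: min_ghg
budget_cap: 9.00
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
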
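id: ASIAN_G
description: Asian-style pattern minimizing GHG emissions under NZ$9/day.
objective: min_ghg
budget_cap: 9.00
per_food_min:
  rice: 200
  vegetable_oil: 14
  carrots: 50
  cabbage: 50
  broccoli: 50
  onion: 50
  bok_choy: 50
  salt: 3
price_overrides:
  rice: 0.18
category_constraints:
  - name: vegetables_asian
    any_of: [vegetable]
    none_of: [starchy_root, juice]
    total_min: 500
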
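id: ASIAN
description: >
  Least-cost Asian-style pattern: rice (>=200 g, bulk price $0.18/100 g in
  this scenario only), stir-fry oil (>=14 g), total vegetables >=500 g with
  five named vegetables at >=50 g each; salt for cooking.
objective: min_cost
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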
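id: C2
description: >
  Least-cost diet with a standard porridge breakfast and the flour tied to
  vegetable oil (7:1) so it can be cooked into flatbreads; salt for cooking.
objective: min_cost
per_food_min:
  oats: 39
  skim_milk_powder: 25
  salt: 4.5
linked_ratios:
  - {food_a: flour_wholemeal, food_b: vegetable_oil, ratio_a_to_b: 7}
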
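id: G3
description: Minimize GHG emissions under NZ$9/day with a porridge breakfast.
objective: min_ghg
budget_cap: 9.00
per_food_min:
  oats: 39
  skim_milk_powder: 25
  salt: 1.5
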
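id: NZ_M
description: >
  Familiar "mince on toast" evening meal (beef mince, onion, carrot, another
  vegetable, a little flour, a toast slice) plus the standard porridge
  breakfast (with sugar) and sandwich lunch; everything else optimized for
  cost.
objective: min_cost
per_food_min:
  beef_mince: 125
  onion: 28
  carrots: 15
  flour_wholemeal: 8
  bread_wholemeal: 140   # 1 toast slice (28 g) + 4 sandwich slices (112 g)
  oats: 39
  skim_milk_powder: 25
  sugar: 7
  cheese: 24
  peanut_butter: 25
  margarine: 20
  apple: 130
  salt: 3.5
category_constraints:
  - name: other_vegetable
    any_of: [vegetable]
    none_of: [starchy_root]
    exclude_ids: [onion, carrots]
    total_min: 40
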
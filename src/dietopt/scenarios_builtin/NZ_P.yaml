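id: NZ_P
description: >
  Pacific-theme evening meal (taro, canned tuna, lite coconut cream, onion,
  oil) plus the standard breakfast and lunch; everything else optimized for
  cost.
objective: min_cost
per_food_min:
  taro: 104
  canned_tuna: 77
  coconut_cream: 222
  onion: 14
  vegetable_oil: 7
  oats: 39
  skim_milk_powder: 25
  sugar: 7
  bread_wholemeal: 112
  cheese: 24
  peanut_butter: 25
  margarine: 20
  apple: 130
  salt: 3.5
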
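id: G4
description: >
  Minimize GHG emissions under NZ$9/day on a fully vegan diet (no dairy,
  eggs, fish or meat).
objective: min_ghg
budget_cap: 9.00
excluded_tags: [animal_product, dairy_product, fish, meat, egg]
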
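id: G2
description: Minimize GHG emissions while keeping cost under NZ$9 per day.
objective: min_ghg
budget_cap: 9.00
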
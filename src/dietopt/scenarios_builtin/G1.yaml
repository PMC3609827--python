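id: G1
description: Minimize GHG emissions while keeping cost under NZ$5 per day.
objective: min_ghg
budget_cap: 5.00
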
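id: C1
description: Minimize daily food cost while meeting all nutrient requirements.
objective: min_cost
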
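id: C3
description: >
  Least-cost diet requiring only minimal cooking skills: foods that need
  real cooking know-how (flours, dried pulses, semolina, couscous) are
  excluded.
objective: min_cost
excluded_tags: [requires_cooking_skill]
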
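id: C4
description: >
  Least-cost diet with a high vegetable intake: at least 412 g/day of
  vegetables excluding starchy root crops and juices.
objective: min_cost
category_constraints:
  - name: vegetables_high
    any_of: [vegetable]
    none_of: [starchy_root, juice]
    total_min: 412
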
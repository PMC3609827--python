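# Constraints shared by every built-in scenario.
#
# Variety caps on foods that otherwise dominate purely on cost/nutrition:
# flour, pasta and oats at 240 g/day each; no more than 200 g of any one
# vegetable (fresh, frozen or canned); added sugar capped at 60 g/day
# (half a typical male intake); kiwifruit capped like a vegetable;
# peanut butter and vegetable oil capped at realistic daily amounts.
# Every selected non-condiment food must reach at least 10 g/day unless a
# recipe pins its amount explicitly.
min_if_included: 10
added_sugar_max: 60
per_food_max:
  flour_wholemeal: 240
  flour_white: 240
  pasta: 240
  oats: 240
  sugar: 60
  kiwifruit: 200
  peanut_butter: 100
  vegetable_oil: 60
category_constraints:
  - name: per_vegetable_cap
    any_of: [vegetable]
    per_member_max: 200
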
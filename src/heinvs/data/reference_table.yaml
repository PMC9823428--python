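# Default component standards for the Healthy Eating Index-NVS scoring engine.
#
# Each component is scored against a German Nutrition Society (DGE)
# reference amount in grams/day.  Adequacy components earn points in
# proportion to intake up to the reference; moderation components hold full
# points at or below the reference and lose points linearly, reaching zero
# at zero_point_multiple x reference.
#
# The vegetables (400 g/d) and fruits (250 g/d) references are the DGE
# recommendations; the remaining amounts are DGE-plausible placeholder
# standards and are meant to be edited in place if a different published
# table is to be used.  max_points must stay 15/15 for vegetables/fruits and
# 10 for the other eight components (total 110).
components:
  - component: vegetables
    max_points: 15
    reference_amount: 400.0     # g/day, DGE recommendation
    direction: adequacy
  - component: fruits
    max_points: 15
    reference_amount: 250.0     # g/day, DGE recommendation
    direction: adequacy
  - component: grains
    max_points: 10
    reference_amount: 300.0     # g/day bread/cereals/potatoes (placeholder)
    direction: adequacy
  - component: dairy
    max_points: 10
    reference_amount: 250.0     # g/day milk & dairy (placeholder)
    direction: adequacy
  - component: fish
    max_points: 10
    reference_amount: 30.0      # g/day, ~1-2 portions/week (placeholder)
    direction: adequacy
  - component: beverages
    max_points: 10
    reference_amount: 1500.0    # g/day low-energy drinks, >=1.5 L (placeholder)
    direction: adequacy
  - component: meat
    max_points: 10
    reference_amount: 86.0      # g/day, ~600 g/week upper bound (placeholder)
    direction: moderation
    zero_point_multiple: 2.0
  - component: eggs
    max_points: 10
    reference_amount: 25.0      # g/day, ~3 eggs/week (placeholder)
    direction: moderation
    zero_point_multiple: 2.0
  - component: spreadable_fats
    max_points: 10
    reference_amount: 30.0      # g/day (placeholder)
    direction: moderation
    zero_point_multiple: 2.0
  - component: alcohol
    max_points: 10
    reference_amount: 10.0      # g ethanol/day, tolerable-intake guide (placeholder)
    direction: moderation
    zero_point_multiple: 2.0
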
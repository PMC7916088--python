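# Margarine-like category: unimodal saturated fat, three salted offers
# (low / medium / highly salted), low sugars and protein, fiber rarely
# declared.  Weights mirror the shipped fixture's planted group sizes.
categories:
  - label: margarine and other blends
    basis: solid_per_100g
    n: 850
    nutrients:
      saturated_fat:
        family: truncnorm
        components:
          - {mean: 12.0, sd: 3.5, weight: 1.0}
      total_sodium:
        family: truncnorm
        components:
          - {mean: 0.135, sd: 0.032, weight: 0.314}
          - {mean: 0.405, sd: 0.032, weight: 0.345}
          - {mean: 0.675, sd: 0.032, weight: 0.341}
      total_sugars:
        components:
          - {mean: 0.6, sd: 0.3, weight: 1.0}
      protein:
        components:
          - {mean: 0.5, sd: 0.3, weight: 1.0}
      fiber:
        missing_rate: 0.7
        components:
          - {mean: 0.3, sd: 0.2, weight: 1.0}
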
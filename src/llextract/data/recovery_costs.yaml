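# Economic evaluation of the butyric acid recovery train (extractor +
# three distillation columns). Amounts in million USD; utilities per annum.
# Product rate is the final column's bottoms stream, kg/h.
payout_years: 5
hours_per_year: 8000
product_rate_kg_h: 265
investment:
  extractor column: 0.247
  extractor trays: 0.015
  extractor preheater/cooler: 0.123
  dist I column: 0.128
  dist I trays: 0.006
  dist I reboiler: 0.078
  dist I condenser: 0.069
  dist I preheater/cooler: 0.083
  dist II column: 0.094
  dist II trays: 0.004
  dist II reboiler: 0.032
  dist II condenser: 0.061
  dist II preheater/cooler: 0.003
  dist III column: 0.055
  dist III trays: 0.002
  dist III reboiler: 0.009
  dist III condenser: 0.022
  dist III preheater/cooler: 0.001
utility:
  dist I steam: 0.209
  dist I coolant: 0.002
  dist II steam: 0.052
  dist II coolant: 0.002
  dist III steam: 0.007
  dist III coolant: 0.001
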
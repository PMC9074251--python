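{
  "description": "Printed streams of the 21-stage wastewater-polishing extractor (tridecanol removes residual ester before water recycle); mass fractions, kg/h.",
  "components": ["water", "acetic acid", "butyric acid", "octyl acetate", "tridecanol"],
  "molar_mass": [18.015, 60.052, 88.11, 172.26, 200.36],
  "basis": "mass",
  "flow_units": "kg/h",
  "streams": [
    {"label": "wastewater", "flow": 9682, "composition": [0.9948, 0.0037, 0.0002, 0.0013, 0.0]},
    {"label": "solvent", "flow": 150, "composition": [0.0, 0.0, 0.0, 0.0, 1.0]},
    {"label": "raffinate", "flow": 9644, "composition": [0.9962, 0.0037, 0.0001, 0.0, 0.0]},
    {"label": "extract", "flow": 187.6, "composition": [0.1283, 0.0028, 0.0010, 0.0692, 0.7987]}
  ]
}
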
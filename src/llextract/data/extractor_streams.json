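{
  "description": "Printed inlet/outlet streams of the 32-stage broth extractor (feed includes the recycle); mole fractions, kmol/h.",
  "components": ["water", "acetic acid", "butyric acid", "octyl acetate"],
  "molar_mass": [18.015, 60.052, 88.11, 172.26],
  "basis": "mole",
  "flow_units": "kmol/h",
  "streams": [
    {"label": "feed", "flow": 545.3, "composition": [0.9929, 0.0014, 0.0058, 0.0]},
    {"label": "solvent", "flow": 49.3, "composition": [0.0, 0.0, 0.0001, 0.9999]},
    {"label": "extract", "flow": 55.9, "composition": [0.0616, 0.0019, 0.0558, 0.8807]},
    {"label": "wastewater", "flow": 538.7, "composition": [0.9986, 0.0012, 0.0, 0.0001]}
  ]
}
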
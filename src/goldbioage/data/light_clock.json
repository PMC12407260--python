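{
  "schema": "goldbioage-clock/1",
  "provenance": "light-published",
  "coefficients": {
    "creatinine": 8.3313,
    "glucose": 0.8270,
    "log_crp": 5.7305
  },
  "constant": -13.5298,
  "reference_values": null,
  "beta1": null,
  "units_note": "Coefficients apply to the published measurement scales (serum creatinine, glucose, natural-log C-reactive protein); no unit conversion is performed."
}
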
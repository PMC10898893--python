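{
  "enzalutamide": {
    "regimen_name": "enzalutamide",
    "tablet_strength": 40.0,
    "daily_dose": 160.0,
    "price_per_mg": 2163.33,
    "currency": "COP"
  },
  "apalutamide": {
    "regimen_name": "apalutamide",
    "tablet_strength": 60.0,
    "daily_dose": 240.0,
    "price_per_mg": 1356.64,
    "currency": "COP"
  },
  "_metadata": {
    "source": "Regulated maximum prices (Circular 13/2022, Colombia); monthly therapy prices as printed use a period as thousands separator ($10,383.984 COP means 10,383,984 COP)."
  }
}
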
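{
 "constructs": [
  {"name": "Unmodified", "n_cycles": 40},
  {"name": "3tC", "n_cycles": 40}
 ],
 "protocol": {"velocity": 50.0, "noise_sigma_f": 0.2},
 "reference": "Unmodified",
 "seed": 1
}
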
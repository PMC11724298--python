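{
 "constructs": ["Unmodified", "1tC", "2tC", "2tC-Stack", "3tC"],
 "protocol": {"velocity": 50.0, "noise_sigma_f": 0.2},
 "reference": "Unmodified",
 "seed": 1
}
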
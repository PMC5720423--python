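energy_keV,intensity
27.202,0.406
27.472,0.757
30.98,0.202
31.71,0.0439
35.492,0.0668
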
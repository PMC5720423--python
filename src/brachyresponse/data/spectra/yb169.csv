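energy_keV,intensity
49.772,0.2021
50.742,0.3580
57.5,0.1140
59.3,0.0305
63.121,0.4405
93.614,0.02571
109.780,0.1739
118.190,0.0187
130.523,0.1138
177.214,0.2232
197.957,0.3593
261.078,0.01687
307.737,0.1005
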
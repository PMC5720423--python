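# Bare I125_TG43U1 line source centered in a 20 cm radius x 40 cm PMMA cylinder;
# transverse-axis scoring shells 0.5 mm x 0.5 mm at 0.5-15 cm.
run:
  n_histories: 2000000
  seed: 20100728
  batches: 10
  pcut_keV: 1.0
source:
  id: I125_TG43U1
  kind: bare_line
  active_length_cm: 0.3
phantom:
  material: PMMA
  radius_cm: 20.0
  height_cm: 40.0
tally:
  distances_cm: [0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0, 13.0, 14.0, 15.0]
  thickness_cm: 0.05
  height_cm: 0.05
  energy_bin_keV: 0.5
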
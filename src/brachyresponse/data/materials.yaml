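# Material registry: element mass fractions, density (g/cm^3) and the
# tabulated effective atomic number / electron density constants for the
# detector materials and water.  z_eff and z_over_a are stored reference
# values; the cross-section mixture uses the element fractions only.
water:
  density: 1.0
  z_eff: 7.5
  z_over_a: 0.555
  elements: {1: 0.111894, 8: 0.888106}
LiF:
  density: 2.635
  z_eff: 8.27
  z_over_a: 0.462
  elements: {3: 0.267585, 9: 0.732415}
Li2B4O7:
  density: 2.44
  z_eff: 7.4
  z_over_a: 0.485
  elements: {3: 0.082085, 5: 0.255710, 8: 0.662205}
Al2O3:
  density: 3.97
  z_eff: 10.2
  z_over_a: 0.491
  elements: {13: 0.529251, 8: 0.470749}
diamond:
  density: 3.5
  z_eff: 6.0
  z_over_a: 0.496
  elements: {6: 1.0}
silicon:
  density: 2.33
  z_eff: 14.0
  z_over_a: 0.499
  elements: {14: 1.0}
air:
  density: 0.0012
  z_eff: 7.6
  z_over_a: 0.499
  elements: {6: 0.000124, 7: 0.755267, 8: 0.231781, 18: 0.012828}
PMMA:
  density: 1.19
  z_eff: 6.56
  z_over_a: 0.5394
  elements: {1: 0.080541, 6: 0.599846, 8: 0.319613}
polystyrene:
  density: 1.06
  z_eff: 5.74
  z_over_a: 0.5377
  elements: {1: 0.077421, 6: 0.922579}
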
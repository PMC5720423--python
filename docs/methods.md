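# Methods

## Physical model

The quantity computed is the relative absorbed-dose energy response
correction R of a detector material: its dose-to-water dose ratio at
the source quality divided by the same ratio in the Co-60 calibration
beam. Two approximations reduce this to quantities a photon-only
Monte Carlo can provide:

1. **Collision kerma ≈ absorbed dose.** At 27–308 keV the secondary
   electrons have sub-millimeter ranges in condensed media, so
   charged-particle equilibrium holds on the 0.5 mm scale of the
   scoring shells and electrons are never transported. Consequently
   the engine has no electron cutoff parameters at all; the only
   transport cutoff is the photon cutoff (default 1 keV, the floor of
   the cross-section tables).
2. **Analytic Co-60 denominator.** At 1.25 MeV Compton scattering
   dominates every material involved and the detectors act as large
   photon cavities; the dose ratio then equals the mass
   energy-absorption coefficient ratio. `analysis/01` shows the μ_en/ρ
   ratios agree with the electron-density ⟨Z/A⟩ ratios to ≤ 0.7%, so
   the denominator is evaluated directly from the tables at 1250 keV
   instead of simulating the beam. (A `parallel_beam` source model is
   provided for users who want the explicit beam geometry.)

The unperturbed-fluence assumption is made for R itself (no detector in
the phantom when scoring the numerator); the perturbation is then
quantified separately as a self-attenuation factor by modeling the
detector as concentric shells and repeating the run (below).

## Transport engine

Analog photon transport in RZ (nested cylindrical rings × axial slabs)
geometry, vectorized over photons with numpy:

* Free paths are drawn from the residual optical depth, carried across
  region boundaries (equivalent to resampling by memorylessness).
  Ray–cylinder crossings are solved exactly (quadratic), regions follow
  a half-open [lower, upper) convention, and boundary moves overshoot
  by 10⁻⁷ cm before the region is re-identified from coordinates.
* Channel selection uses the packaged partial cross sections.
  Photoelectric absorption ends the history (fluorescence is neglected:
  K-edges of all phantom constituents are below the 1 keV cutoff, and
  Si/Al/Ar K-fluorescence carries ≲ 0.3% of the absorbed energy at the
  source energies — this is folded into μ_en instead).
* Compton scattering: Klein–Nishina sampling (Kahn-style two-branch
  rejection) followed by rejection on the material's incoherent
  scattering function S(x). This bound-Compton step keeps the angular
  law consistent with the S-corrected incoherent cross section used for
  channel selection; without it the scattered spectrum is too hard and
  the I-125 fluence-weighted mean energy drifts upward with depth
  instead of staying flat. No Doppler broadening.
* Rayleigh scattering: x² sampled from the cumulative of F²(x) with a
  Thomson (1+cos²θ)/2 rejection; with F ≡ 1 (toy materials) this is
  exactly Thomson sampling.
* Track-length fluence estimator: each flight segment deposits its
  exact chord length through every scoring shell (annulus ∩ slab ∩
  segment, computed in closed form) into the energy bin of the
  photon's current energy. Default bins are 0.5 keV wide from the
  cutoff to the highest source line; line energies are therefore
  represented by their bin center, a ≤ 0.25 keV shift whose effect
  cancels to < 0.1% in detector-to-water kerma ratios.
* Uncertainties: histories are split into 10 batches; every derived
  quantity (kerma, R, mean energy, self-attenuation) carries the 1σ
  batch standard error. Ratio uncertainties combine relative errors in
  quadrature, which is conservative for ratios formed from the same
  tally (the fluence-amplitude noise is common to numerator and
  denominator).
* No variance reduction: the analog estimator stays unbiased and every
  acceleration is pure vectorization. Determinism: a single PCG64
  stream seeded from the run configuration; identical configurations
  give bit-identical tallies.

## Cross-section data

No cross-section library is assumed at run time; all coefficients ship
as plain-text CSV per element (H, Li, B, C, N, O, F, Al, Si, Ar) on a
common 123-point logarithmic grid over 1–1500 keV, densified in the
I-125 band (20–40 keV) and pinned at the source line energies and
1250 keV so the quantities that matter are table look-ups, not
interpolations. `scripts/build_element_tables.py` reconstructs them
offline from three ingredients:

* **Coherent**: Thomson cross section × atomic form factors from the
  International Tables (IT92) Gaussian fits, with the constant term
  replaced by a hydrogenic 1s shape so F → 0 at large momentum
  transfer; integrated numerically. (The published IT92 fit for
  nitrogen is unusable for this purpose; N is synthesized as a
  normalized geometric mean of C and O.)
* **Incoherent**: Klein–Nishina × incoherent scattering function
  S(x,Z) built from the same Gaussian decomposition (exact 1−f² for
  hydrogen). The decomposition provably overestimates S (it drops the
  off-diagonal Waller–Hartree terms), so a single limit-preserving
  exponent S′ = Z·(S/Z)^γ, γ = 1.414, is calibrated once against the
  transcribed XCOM water incoherent coefficient at 30 keV.
* **Photoelectric**: the residual of transcribed standard
  total-attenuation anchors (NIST element tables, 4–110 keV) after
  subtracting the two scattering models, smoothed by a per-element
  quadratic log-log fit with power-law tails; Li, B and F, whose
  anchors were not trusted, come from a ln σ vs ln Z regression over
  the anchored elements. K-edges of Al/Si/Ar are continued below the
  edge by a generic jump ratio (those energies are below any
  practically transported photon).
* **μ_en**: photoelectric (minus a small K-fluorescence escape term
  for Al/Si/Ar) plus the Klein–Nishina energy-transfer fraction times
  the incoherent coefficient — both taken from the *uncalibrated*
  decomposition, which reproduces the transcribed Hubbell–Seltzer
  water and air μ_en tables to ~1% (air to ~5% at 40–80 keV, where
  the nitrogen photoelectric residual is weakest). Carrying transport
  channels of XCOM flavor and μ_en of Hubbell–Seltzer flavor mirrors
  standard dosimetry practice. Radiative (bremsstrahlung) losses of
  secondary electrons (< 0.5% for low Z below 1.5 MeV) and pair
  production (< 1% of the total at 1.5 MeV) are neglected; the stored
  total is exactly the sum of the three channels.

Mixtures use the additive mass-fraction rule; compound registry values
(Z_eff, ⟨Z/A⟩, density) are stored constants. Validation against
transcribed compound tables: water μ/ρ within 1%, water μ_en within
1.3%, interaction fractions in water at 27 keV of 47.3/41.0/11.7%
(photoelectric/incoherent/coherent). All interpolation is log-log
linear.

## Sources

Bare, unencapsulated geometries only — an isotropic line source
(default active length 0.3 cm; no standard value exists for a "bare
line source", and the results are insensitive to it), an isotropic
point source, and a parallel circular beam. Packaged spectra: the
five-line TG-43U1 consensus I-125 spectrum (intensity-weighted mean
28.37 keV); a 13-line Yb-169 spectrum (principal γ lines plus Tm K
x-rays, standard emission probabilities, 2.18 photons/decay); Co-60 as
two equal lines at 1170/1330 keV (reference energy 1250 keV).
Encapsulated clinical sources (seed capsules, HDR source cables) are
out of scope; their filtration can be emulated only crudely by
user-configured geometry, and no encapsulated-source values are
asserted anywhere in the package.

## Study conditions and problem sizes

The default experiment presets fix the conditions: a 20 cm radius ×
40 cm height phantom cylinder (water, PMMA C₅H₈O₂ ρ=1.19, or
polystyrene C₈H₈ ρ=1.06), scoring shells 0.5 mm × 0.5 mm at sixteen
transverse distances 0.5–15 cm, 1 keV photon cutoff, 10 batches, seed
recorded in the preset. Default history counts (2×10⁶ per run;
4×10⁶ for the I-125 acceptance run, 3×10⁶ per self-attenuation run)
give ≤ 0.5% kerma uncertainties at 1 cm and run in seconds to a
minute on one CPU; they are the package's chosen desk scale, and all
statistical tolerances in the tests are stated at these sizes.

Self-attenuation detector models: silicon diode = 60 μm sensitive
shell between 0.0225 cm substrate shells, 1 mm height (a "0.225 cm"
substrate, as sometimes quoted for this diode type, contradicts the
0.45 mm total substrate of the actual device; 0.0225 cm per side is
used); LiF and Al₂O₃ = 1 mm × 1 mm shells. The factor is kerma with
the detector modeled over collision kerma without it, both scored in
the sensitive shell.

## What the toy physics does and does not show

`brachyresponse.toy` provides materials with prescribed constant or
power-law channels and closed-form oracles (attenuated inverse-square
fluence, Klein–Nishina reference pdf, Thomson limit). The oracle suite
demonstrates that the transport machinery — emission, free paths,
boundary crossings, channel selection, track-length scoring, batching —
is exact against closed forms, and that errors scale as 1/√N. It
cannot validate the *data*: agreement of real-material results with
published values depends additionally on the reconstructed cross
sections, whose fidelity is established separately by the compound
anchors above (≈ 1% for water attenuation and μ_en, a few per cent for
individual partial channels of other elements).

## Known limitations

* Reconstructed cross sections, not a verbatim XCOM/Hubbell–Seltzer
  transcription: partial-channel errors of a few per cent are possible
  off the anchor energies, and the Al₂O₃ self-attenuation factor comes
  out 0.872 vs the published 0.850 (the silicon 0.889 and LiF 0.975
  factors are reproduced within ~1%).
* The exact Yb-169 line spectrum used in the original study is not
  printed there; the packaged standard spectrum is a stand-in and the
  Yb-169 comparisons carry correspondingly wider tolerances.
* No Doppler broadening, no fluorescence transport, no electron
  transport, no pair production, RZ symmetry only, analog only.
* The energy response R corrects absorbed-dose energy dependence only;
  intrinsic detector energy dependence (TL efficiency, diode
  electronics) is explicitly out of scope.
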
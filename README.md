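# brachyresponse

Monte Carlo calculation of the **relative absorbed-dose energy response
correction** of solid-state dosimeters around low-energy brachytherapy
sources.

Solid-state detectors (LiF and Li₂B₄O₇ TLDs, Al₂O₃, diamond, silicon
diodes) and air-filled chambers are calibrated in a Co-60 beam but used
to measure dose around I-125 (~28 keV) and Yb-169 (~50–308 keV)
sources, where their response per unit water dose can differ from the
calibration condition by a factor of up to ~8. This package computes
the correction from first principles for medical physicists who need
it per detector, per source, per depth and per phantom material.

## The model

For a detector material *det* at beam quality *Q*, the correction is

```
        (D_det / D_wat)_Q
R  =  ─────────────────────
      (D_det / D_wat)_Co-60
```

Under charged-particle equilibrium (secondary-electron ranges are ≪ mm
at these energies) absorbed dose is approximated by collision kerma,

```
K_m = ∫ Φ(E) · E · (μ_en(E)/ρ)_m dE ,
```

so the numerator is formed from the photon fluence spectrum Φ(E) scored
by an analog photon-transport Monte Carlo in the phantom, and the
denominator by the mass energy-absorption coefficient ratio at 1.25 MeV
(at Co-60 energies all of these detectors behave as large photon
cavities, so the dose ratio reduces to the μ_en/ρ ratio; see
`analysis/01_reference_ratios.py`).

The engine transports photons only, in cylindrical RZ geometry:
photoelectric absorption terminates a history, Compton scattering uses
Klein–Nishina sampling with an incoherent-scattering-function rejection
(Waller–Hartree bound Compton), Rayleigh scattering uses atomic form
factors. Fluence is estimated with a track-length estimator in 0.5 mm ×
0.5 mm shells on the source's transverse axis; ten batches give the
statistical uncertainty. Photon cross sections and μ_en/ρ for every
element involved are packaged as plain-text tables (see
`docs/methods.md` for their construction and provenance).

## Worked example

Response corrections for a bare I-125 line source in a 20 cm radius
water phantom (two million histories, ~5 s):

```bash
brachyresponse respond --preset i125_water --histories 2000000 \
    --seed 1 --detectors LiF,silicon,diamond --out response.csv
```

prints, per scoring distance (excerpt):

```
material   label  distance_cm      R  rel_unc
   water d=0.5cm       0.5000 1.0000   0.0000
     LiF d=0.5cm       0.5000 1.3880   0.0055
     LiF   d=1cm       1.0000 1.3880   0.0087
 silicon   d=1cm       1.0000 8.3643   0.0087
 diamond   d=1cm       1.0000 0.4728   0.0087
```

Read: a LiF TLD in water 1 cm from a bare I-125 source absorbs 1.39×
more dose relative to water than it did in its Co-60 calibration beam,
a silicon diode 8.36× — measured TL or diode readings must be divided
by these factors. The corrections are independent of distance for
I-125 (max/min ≤ 1.007 over 0.5–15 cm at this history count); for Yb-169 they are not (try
`--preset yb169_water`: R for silicon rises from ~2.7 at 0.5 cm to
~4.2 at 15 cm as the spectrum softens with depth).

The numbered scripts under `analysis/` reproduce the full study —
reference ratios, I-125 and Yb-169 response tables, mean energies,
detector self-attenuation, solid-phantom ratios — and write their
tables to `results/`. `brachyresponse validate` runs the closed-form
oracle suite (inverse-square and attenuation benchmarks, Klein–Nishina
sampler statistics, 1/√N error scaling).

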
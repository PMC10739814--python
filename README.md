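# pgcam — Compton-camera imaging of boron-neutron-capture prompt gammas

In boron neutron capture therapy (BNCT) the delivered dose depends on the
local rate of the capture reaction ¹⁰B(n,α)⁷Li, which is hard to measure:
neither the in-vivo boron concentration nor the thermal-neutron flux is
directly observable during treatment. The excited ⁷Li product, however,
emits a 478 keV prompt gamma (PG) in ~94% of captures, so imaging the PG
emission maps the capture reactions themselves. A stacked Si/CdTe Compton
camera can do this without a collimator — if its energy resolution separates
the PG line from the 511 keV annihilation background only 33 keV (~7%) away.

`pgcam` is a synthetic-data and analysis pipeline for that measurement. It
provides, as a tested library plus numbered analysis drivers:

- **Compton physics** — for a photon that deposits `E1` in a Si scatterer
  and is absorbed with `E2` in a CdTe layer, the scattering angle follows
  from `cos θ = 1 − m_ec²(1/E2 − 1/(E1+E2))` with `m_ec² = 511 keV`; each
  event constrains its source to a cone (apex at the scatterer hit, axis
  from absorber to scatterer hit, half-angle θ).
- **A calibrated detector model** — Gaussian energy blur with
  `FWHM(E) = FWHM(662 keV)·√(E/662)` anchored at 2.2% (662 keV), lateral hit
  blur, and a residual axis tilt calibrated by bisection so the simulated
  angular resolution measure (ARM) reproduces 5.4° FWHM at 662 keV.
- **A seeded Monte-Carlo list-mode generator** for the measurement scenes: a
  B₄C target at X = −12/−2/+8 cm on the plane Z = 13 cm, 511 keV
  annihilation gammas, the 558 keV Cd-capture and 478 keV circuit-board
  lines from inside the camera, a scattered-gamma continuum, and a 2.2 MeV
  hydrogen-capture line for the underwater-target scene.
- **Event selection**: total energy in 468–488 keV (excluding the 511 keV
  peak), `E1 < 200 keV`, and a CdTe-fluorescence veto (20–35 keV deposits in
  the last scatterer + first absorber pair).
- **Spectroscopy**: photopeak fits and the net/gross peak ratio with a
  linear background fitted to the 450–463 / 493–499 keV sidebands.
- **Reconstruction**: Gaussian-weighted cone back-projection onto the target
  plane and list-mode MLEM,
  `λ_j ← (λ_j/s_j) Σ_i t_ij / Σ_m t_im λ_m` with
  `t_ij = exp(−Δ_ij²/2σ_i²)`.
- **Contrast metrics**: pixel-by-pixel background subtraction (graphite
  reference “SIwG”, no-target reference “SIwoT”) and the pixel-value ratio
  PVR = mean(target ROI) / mean(elsewhere) with negative pixels clipped.

## Worked example

The numbered drivers under `analysis/` run the whole study at 1/10 exposure
(720 s per scene) with seed 1:

```sh
python analysis/01_calibrate_camera.py
python analysis/02_simulate_and_select.py
python analysis/03_spectra_net_gross.py
python analysis/04_reconstruct_images.py
python analysis/05_background_subtraction_pvr.py
python analysis/06_worked_examples.py
```

Calibration finds an intrinsic ARM floor of 4.21° from energy and position
blur alone and a residual axis tilt of 2.150° (1σ), verified at 5.38° FWHM
on an independent sample. Simulation and selection then print, per scene,
e.g.

```
b4c_x-2    generated  15085  selected   648  (window -13911, E1 -523, xray -3)
no_target  generated  14966  selected   542  (window -13900, E1 -523, xray -1)
```

(at full 2 h exposure the selected totals are in the 5000–6500 range). The
478 keV net/gross ratio quantifies the PG signal above the persistent
circuit-board peak — highest with the target nearest the neutron source and
at the background level for graphite:

```
b4c_x-12   ratio=0.284 +- 0.032
b4c_x-2    ratio=0.263 +- 0.033
b4c_x8     ratio=0.202 +- 0.037
graphite   ratio=0.180 +- 0.037
no_target  ratio=0.190 +- 0.037
```

Reconstruction places the image maximum at the target for X = −12 and −2 cm
(back-projection argmax (−112.5, 2.5) and (−22.5, 12.5) mm) while the weak
X = +8 cm signal stays near the diffuse background. Background subtraction
raises the contrast for every target scene:

```
b4c_x-12   PVR original=  9.70  SIwG= 19.72  SIwoT= 49.27
b4c_x-2    PVR original= 12.13  SIwG= 19.33  SIwoT= 70.24
b4c_x8     PVR original=  3.59  SIwG=  4.62  SIwoT= 18.46
```

and the closed-form worked quantities print as: 14.5 g of ¹⁰B in 100 g of
natural-abundance B₄C (2.9 g in 20 g), a bench exposure worth 0.9 s of
clinical capture production, and a 5–6° angular resolution subtending
8.7–10.5 mm at 10 cm.

The same stages are scriptable through the `pgcam` CLI
(`simulate`, `select`, `spectrum`, `reconstruct`, `subtract`, `metrics`,
`calibrate`, `run-all`) or in one shot via `pgcam.pipeline.run_pipeline`.

## Documentation

`docs/methods.md` describes the response model, the generator's
assumptions and presets, numerical choices, and known limitations.
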
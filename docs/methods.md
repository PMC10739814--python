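# Methods

## The measurement being emulated

A stacked Compton camera (eight 50 × 50 × 0.75 mm Si scatterer layers above
four CdTe absorber layers) views a B₄C target on the plane Z = 130 mm in a
thermal-neutron field. Each recorded event is a two-hit coincidence: a
Compton scatter in one Si layer (deposit `E1`) followed by photo-absorption
in one CdTe layer (deposit `E2`). Under the full-absorption assumption the
scattering angle is

    cos θ = 1 − m_ec² (1/E2 − 1/(E1+E2)),   m_ec² = 511.0 keV,

and the event constrains its source to a cone. Energy pairs with
|cos θ| > 1 are flagged (NaN), never clamped or raised: unfiltered streams
legitimately contain them, and the reconstructor skips them with a count.

The quantity of interest is the 478 keV prompt gamma (PG) from
¹⁰B(n,α)⁷Li* — emitted in 94% of captures — imaged against backgrounds that
include the 511 keV annihilation line only 33 keV away.

## Detector response model

Three blur channels, applied to simulated events:

| channel | form | default | why |
|---|---|---|---|
| energy | Gaussian, FWHM(E) = FWHM_ref·√(E/E_ref) | 2.2% at 662 keV | single published calibration point; √E is the statistical limit |
| hit position | lateral Gaussian per hit | σ = 1.0 mm | strip pitch unpublished; see below |
| axis tilt | Gaussian rotation of the measured scatterer→absorber axis | calibrated | absorbs everything not modelled explicitly (Doppler broadening, depth effects) |

FWHM and σ convert by 2√(2 ln 2) ≈ 2.3548 throughout.

The angular resolution measure (ARM) is, per event, the geometric angle
(cone axis to the known source direction) minus the kinematic angle from
the energies; its distribution's FWHM is the angular resolution.
`calibrate_angular_blur` bisects the residual tilt until the simulated ARM
FWHM at 662 keV matches the 5.4° specification within 0.05°, using common
random numbers across evaluations so the objective is smooth and the result
deterministic for a given seed. If the requested target lies below the
intrinsic floor (tilt = 0) the calibration raises an error reporting that
floor.

Two defaults deserve comment:

- **Layer spacings** (4 mm Si pitch, 30 mm Si–CdTe gap, 4 mm CdTe pitch)
  are not published for this instrument; they are plausible for a compact
  stack, are configurable, and influence results only through the ARM
  calibration, which re-absorbs them into the residual tilt.
- **σ_pos = 1.0 mm.** With these spacings, a 1.5 mm lateral blur alone
  drives the intrinsic ARM floor to ≈ 6.2° at 662 keV — above the 5.4°
  target, leaving the calibration nothing to do and no feasible solution.
  At 1.0 mm the floor is ≈ 4.2°, and the calibrated tilt (≈ 2.15° 1σ)
  closes the gap.
- **Energy scaling of the ARM**: per-event cone widths at other energies use
  FWHM_ARM(E) = 5.4°·√(662/E) — resolution degrades toward low energy
  because the kinematic leverage |dθ/dE| grows faster than the energy blur
  shrinks. At the 478 keV operating point this gives σ ≈ 2.70°.

The calibrated ARM distribution retains a small physical skew
(mean ≈ +0.17° at 662 keV, ~1/13 of σ): blur propagated through the
nonlinear kinematics is not exactly symmetric. Tests assert near-symmetry
(|mean| < 0.3°), not exact symmetry.

## Synthetic scenes and the event generator

The generator is phenomenological: no neutron transport, no attenuation.
Each scene component emits recorded two-hit events directly at a preset
rate (Poisson in the exposure). Line components follow the physics of the
measurement — emission point from the component's spatial distribution,
uniform scatterer layer and interaction point (true interaction-depth
distributions are unpublished; layer identity only matters for the X-ray
veto), Klein–Nishina scattering angle, kinematic energy split with full
absorption, absorber-plane intersection with rejection of rays missing the
50 mm square — then the response blurs. The axis tilt rotates the measured
axis about the scatterer hit and re-intersects the absorber plane, so hits
stay on their layers. Continuum components instead draw the total energy
uniformly on 300–600 keV, split it randomly between the hits
(E1/E_tot ~ U(0.02, 0.7)), and place both hits uniformly on random layers:
deliberately uncorrelated "fake cones" that produce flat spectral sidebands
and a diffuse image background.

Preset intensities (events/s: PG 0.22 × flux factor; annihilation 1.5;
Cd 558 keV 1.0; circuit-board 478 keV 0.23; continuum 18.0) are free
parameters fixed once so that (a) every 2 h scene yields ~5000–6500
selected events and (b) the X = +8 cm target sits near the background level
in the reconstruction, as in the emulated experiment. Relative thermal-flux
factors at X = −120/−20/+80 mm are 1.0/0.8/0.12: the first two express the
flux falling along +X; the third is deliberately small so the X = +8 target
is *not* cleanly distinguishable (at 0.4 it still was). The graphite scene
is the background set plus a 0.5% continuum increase (the block scatters
gammas but emits no PGs); the water-tank scene adds a 2.2 MeV
hydrogen-capture line in a 10 cm cube and a slab target, plus 20% more
continuum. An optional intrinsic line FWHM (Doppler broadening of the ⁷Li*
emission, e.g. 15 keV) can be convolved into the emission energy; it
defaults to 0.

Seeding: one global 64-bit seed; every component draws from its own stream
derived from (seed, label), and the final event order is a sort on
per-event random keys from those streams. Consequences used by the analysis:
removing a component leaves all other events (and their relative order)
untouched, and scenes sharing a component at the same intensity share its
event realization exactly. The latter makes the no-target subtraction an
almost exact background cancellation — the idealization behind the clean
SIwoT > SIwG > original contrast ordering; independently measured
acquisitions would decorrelate and weaken it.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: neutron/photon transport and
attenuation, detector efficiency and interaction-depth physics, Si–Si and
CdTe–CdTe or ≥3-hit topologies, partial energy deposits of high-energy
gammas (the 2.2 MeV line is simulated with full absorption, so it never
enters the 468–488 keV window by construction), pile-up and dead time.

## Selection conventions

Window bounds are inclusive on both ends (468 ≤ E_tot ≤ 488 keV); the
scatterer cut is strict (E1 < 200 keV); the CdTe-fluorescence veto is the
inclusive band 20 ≤ E1 ≤ 35 keV applied only in the (last scatterer, first
absorber) layer pair, i.e. the deepest Si layer and the CdTe layer nearest
the Si stack. The boundary conventions are ours (the window's edge behavior
is immaterial at 2.2% resolution); `selection_truth_table` freezes them.
Rules are applied window → E1 → X-ray so per-rule rejection counts are
reproducible; precedence cannot change the surviving set.

## Spectroscopy

Analysis spectra use 2 keV bins over 300–700 keV (binning is a free
choice). The net/gross estimator sums counts in the peak window (gross, raw
window sum, not a fitted area), fits an unweighted straight line to the
450–463 and 493–499 keV sideband bin centers (counts there are of similar
magnitude, so weighting is immaterial), integrates it across the window
(bg), and reports net/gross with a delta-method uncertainty combining
Poisson counting on the gross sum with the sideband-fit covariance (scaled
to the mean sideband count). A negative net is reported as computed and
flagged, never clipped. Photopeak fits are Gaussian + linear baseline by
least squares; non-convergence returns a flagged result.

## Reconstruction

Images are 2-D on the target plane Z = 130 mm (5 mm pixels, ±200 mm).
Back-projection scores pixel j of event i by
`t_ij = exp(−Δ_ij²/(2σ_i²))` where Δ is (geometric angle − cone
half-angle) and σ_i the ARM σ scaled to the assumed 478 keV — a Gaussian
ring rather than a thin-shell cone, because the ARM is the camera's only
stated resolution. MLEM iterates the multiplicative update with uniform
sensitivity s_j = 1 (the field of view is small relative to the camera and
no sensitivity map is given); the Poisson log-likelihood
Σ_i log Σ_m t_im λ_m is logged per iteration and is non-decreasing. The
default is 10 iterations (no stopping rule is published; configurable).

Half-angle convention: the default computes θ from the measured (E1, E2).
The assumed 478 keV initial energy then enters only through σ_i. The
alternative "assumed-initial" convention (cos θ = 1 − 511(1/(478−E1) −
1/478)) is available as a switch; inside the ±10 keV selection window the
two differ by far less than the cone width (median difference < 2° on
selected events).

Known limitation: without a sensitivity map, barely-constrained pixels at
the image border can accumulate spurious MLEM intensity (an occasional
single border pixel exceeding the target blob). `argmax_xy(exclude_border=…)`
exists for robust peak localisation, and ROI-based metrics are insensitive
to it.

## Contrast metrics

PVR clips negative pixels to zero, then divides the mean over pixels whose
centers fall in the target ROI (half-open on high edges) by the mean over
all other pixels of the full grid (no annulus or margin is defined).
Subtraction is pixel-by-pixel between equal-exposure acquisitions with no
normalisation (a `scale` option exists for unequal exposures); negative
pixels are preserved in stored subtracted images — clipping happens only
inside the PVR. PVR tables and the replicate ordering study are computed on
MLEM images (10 iterations): on raw back-projections the diffuse background
dominates and the subtraction orderings are within noise of each other,
while MLEM concentrates the target signal enough for the orderings to be
stable. The qualitative "visible blob" criterion (target-ROI mean above
mean + 2 SD of the non-ROI pixels) is evaluated on 30-iteration MLEM
images: at 10 iterations the centre-weighted background bowl makes
near-centre ROIs trigger regardless of signal.

## Problem sizes

The analysis drivers and the replicate studies run at 1/10 of the full 2 h
exposure (≈ 15 000 generated, ≈ 600 selected events per scene) — the scale
at which the qualitative conclusions are already stable. Calibration and
resolution-recovery computations use 60 000–100 000 point-source events.
The full-exposure pipeline (all six scenes, ≈ 120 000 generated events
each) runs in under a minute per scene on one CPU.
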
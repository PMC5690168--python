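# Methods

`plaquedose` is a desk-scale analog Monte Carlo photon-transport code built
for one problem class: dosimetry of ¹²⁵I COMS eye-plaque brachytherapy of
choroidal melanoma, in a heterogeneous human-eye phantom, with and without
gold nanoparticles (GNPs) mixed into the tumor. This note records the model,
its assumptions, the numerical choices, and what the synthetic scenes do and
do not establish about real treatments.

## Transport model

Photons in 5–35.5 keV are tracked analytically through a
constructive-solid-geometry scene (quadric surfaces; priority-ordered cells;
surface tracking with per-object bounding-sphere early-outs). Interactions:

* **Photoelectric absorption** — full local energy transfer, except that
  K-shell fluorescence of silver, palladium and copper (the only K edges
  between the 5 keV cutoff and the source lines) is emitted and transported:
  the emission probability is the jump-ratio shell participation × the
  Krause fluorescence yield × the Kα/Kβ branching, interpolated on each
  material's energy grid. Gold L x-rays (9.7–13.4 keV) are deposited locally
  by default (`RunConfig.emit_au_l` transports them instead); tissue K
  fluorescence is sub-cutoff and always local.
* **Incoherent scattering** — Klein–Nishina sampling with rejection on the
  material's incoherent scattering function S(x); the electron's energy is
  deposited at the collision site (kerma approximation).
* **Coherent scattering** — inverse-CDF sampling of x² from the cumulative
  form-factor weight with a (1+cos²θ)/2 rejection; no energy loss.
* **Cutoff** — photons falling below 5 keV are terminated with local
  deposition.

Electrons are not transported. At ≤35.5 keV the CSDA range of secondary
electrons in tissue is below ~30 µm, far smaller than the 0.5 mm scoring
cells, so collisional kerma ≈ absorbed dose; this is the engine's main
physics simplification. Doppler broadening, bound-Compton profiles beyond
S(x), polarization, and atomic relaxation cascades beyond single K/L lines
are omitted.

Scoring uses a **track-length kerma estimator**: each flight segment adds
`w·E·ℓ·(μ_en/ρ)` of the scoring medium to every tally region it crosses,
with exact chord lengths. A collision-density estimator is accumulated in
parallel as a cross-check, and the uncollided (first-flight) component is
reported separately, which the analytic oracle tests exploit. Energy
bookkeeping (emitted = deposited + escaped, per batch) is exact to rounding.
Runs are split into batches; quoted errors are standard errors of batch
means. The RNG is numpy's MT19937, seeded once per run inside the kernel:
runs are bit-reproducible, and two scenes run with the same seed share their
random stream (correlated sampling).

## Interaction data

No tabulated cross-section library is shipped with the environment, so the
per-element tables under `plaquedose/data/elements/` are generated once by
`scripts/generate_xs_tables.py` from established analytic atomic physics:

* photoabsorption from Cromer–Liberman f″ (σ_pe = 2 r_e λ f″), with a single
  global renormalization factor 1.035;
* coherent form factors F(x,Z) from the International Tables (1992)
  Cromer–Mann fits, power-law tail beyond the fit range;
* incoherent scattering function S(x,Z) = Z[1 − (F/Z)^q] with q = 1.2 — a
  calibrated generalization of the Waller–Hartree closure (plain closure,
  q = 2, neglects exchange and overestimates S at intermediate momentum
  transfer);
* σ_coh, σ_incoh and the incoherent energy-transfer coefficient by numerical
  integration of the Thomson and Klein–Nishina kernels weighted by F² and S;
* μ_en/ρ = σ_pe·(1 − fluorescence escape) + σ_incoh,tr, with jump-ratio
  subshell participations, Krause yields, and Coster–Kronig–effective L
  yields for Au/Pt.

The two calibration constants (1.035, q = 1.2) were fitted once, jointly,
to nine standard NIST water/air attenuation and energy-absorption
coefficients between 10 and 40 keV; all nine anchors are reproduced within
0.7% (RMS 0.34%). Nothing in the tables is tuned to any benchmark the
package is validated against. Expected absolute accuracy is ~1% for water
and air, and a few percent for high-Z elements (gold, silver), which is the
dominant systematic in the GNP results.

## Source model

The model-6711 seed is a titanium capsule (0.8 mm OD, 0.05 mm wall, 4.5 mm
long, flat end welds) around a 3.0 × 0.5 mm silver rod. Photons start
uniformly on the rod surface (the radioiodine resides in a surface AgI
layer) with isotropic directions and energies from the five-line ¹²⁵I
spectrum (27.202, 27.472, 30.98, 31.71, 35.492 keV). Silver K x-rays are
*not* folded into the emission spectrum; they are produced physically when
primaries are photoabsorbed in the rod. The resulting emitted field is
roughly one-fifth silver fluorescence, consistent with measured 6711
spectra. Flat end welds make the near-axis anisotropy the least accurate
region of the model; transverse-plane quantities are unaffected.

## TG-43 benchmark

Air kerma is scored in dry-air toroidal cells in vacuum (0.05–20 cm);
S_K is the mean of K̇·d² over 1–10 cm and the run aborts if the plateau is
nonconstant beyond 0.5% (or twice the point statistics at reduced history
counts). The dose-rate constant is the transverse water dose rate at 1 cm
(torus of 0.01 cm minor cross-sectional diameter — read as diameter; the
sensitivity is below statistics) divided by S_K. g_L(r) uses the line-source
geometry function with L = 3.0 mm and is normalized exactly at r₀ = 1 cm.
Toroid tallies are revolved *square* cross-sections of half-width equal to
the nominal minor radius (0.008–0.1 cm by radius); at these sizes the
cross-section shape changes the scored dose only at second order, and the
square section needs no quartic ray intersections.

With 10⁷ histories the engine gives Λ ≈ 0.95 cGy h⁻¹ U⁻¹ and a radial dose
function within ±5% of the published single-seed benchmarks across
0.1–10 cm — between the values reported by independent Monte Carlo studies
(0.923–0.942) and the consensus 0.965.

## Eye phantom and plaque

Geometry defaults (cm, origin at the globe center): vitreous inside 0.93;
retina 0.93–1.03 and choroid 1.03–1.13 as water; sclera 1.13–1.23; lens
ellipsoid 0.8 × 0.9 equatorial, 0.25 polar thickness (the polar thickness is
configurable; the default follows the stated specification even though it is
anatomically thin); optic-nerve annulus between cylinder diameters 0.7/0.8
along −z; skull shell 1.505–2.05; a 30 cm water cube around everything (the
globe is centred in the cube; at >13 cm of water the position of the cube
faces is irrelevant to the tallies). The tumor is a spherical-cap dome based
on the inner sclera on the +x (equator-temporal) axis, apex height 5 mm
(apex 6 mm from the exterior scleral surface), basal chord ≈ 11 mm
(configurable; not stated by the benchmark, chosen to match the 16 mm plaque
footprint).

The 16 mm COMS plaque is modelled as spherical caps concentric with the
globe: Silastic carrier 1.23–1.47, Modulay gold-alloy backing 1.47–1.52
(half-angle 40.6°, 4° lip to the sclera). The exact manufacturer seed
coordinates were not available; the package default is a geometrically valid
fully-loaded layout of 13 seeds tangent to the 1.35 cm sphere in two rings
(5 at 13° polar, meridian-oriented; 8 at 31.5°, ring-oriented), editable in
`geometry.SEED_RINGS`. With this layout and the 85 Gy apex prescription the
bare-seeds-in-water point doses reproduce published values at the few-percent
level (center of eye 27.2 vs 27.6 Gy) without any coordinate fitting; the
absolute scleral dose, which sits close to the nearest seeds, is the most
layout-sensitive point (~15%). All *comparative* quantities (plaque effect,
composition effect, DEF) are insensitive to the layout.

Points of interest are small boxes placed inside a single anatomical cell
(coordinates are echoed in every report): sclera under the plaque
(0.5 × 1 × 1 mm at x = 1.20), tumor apex (0.5 mm-thick cell just inside the
dome face), globe center, inner sclera opposite the plaque, optic-nerve head,
lens center, macula. Depth dose uses 48 contiguous 0.5 mm cells along the
plaque axis from the sclera under the plaque to the opposite sclera, with a
cell centered exactly at the 5 mm prescription depth.

## Prescription

Integrated doses assume 85 Gy to the tumor apex over a 100 h implant with
¹²⁵I decay (T½ = 59.4 d), i.e. an effective irradiation time
(1 − e^(−λt))/λ ≈ 97.6 h. The emission rate is calibrated on the
bare-seeds-in-water scenario and then reused unchanged for every other
scenario, so organ doses are directly comparable across configurations.

## Two DEF estimators

The dose-enhancement factor at a point is the ratio of absorbed dose with
the tumor loaded at c mg of gold per gram of tissue (homogeneous mixture,
w_Au = c/(1000+c), density by the inverse mass-fraction rule) to the dose
without. The package computes it two ways, and they answer different
questions:

1. **Transport estimator** (`eye_analysis.def_scan`): two correlated runs
   with the tumor material switched. This is the self-consistent answer: the
   gold both enhances local absorption and attenuates the field, so the
   enhancement at the apex — reached through the full 5 mm of loaded tumor —
   saturates (≈2.8 at 30 mg/g in water), and points beyond the tumor are
   visibly shielded, increasingly so with concentration.
2. **Unperturbed-fluence (kerma-response) estimator**
   (`eye_analysis.def_from_response`): a single unloaded run in which the
   apex cell is additionally scored with the μ_en/ρ of each loaded mixture.
   This is the tally-multiplier style of estimate common in dose-enhancement
   studies: DEF is the μ_en ratio folded over the unperturbed apex spectrum,
   exactly linear in c at low loading, with no self-attenuation and no
   downstream perturbation. It gives ≈2.0 / 2.4 / 3.5 / 5.2 (water) and
   ≈2.0 / 2.4 / 3.4 / 5.0 (eye) at 7/10/18/30 mg/g.

Published DEF tables for this configuration are linear in concentration and
show no concentration dependence at any non-tumor point, i.e. they
correspond to estimator 2; the package therefore reports estimator 2 for
benchmark comparisons while estimator 1 documents the physically complete
picture. The gap between the two (×1.8 at 30 mg/g) is entirely gold
self-attenuation. DEF from either estimator is insensitive to the apex tally
volume (0.5 mm cell vs 1 mm sphere) at fixed position.

## Problem sizes and uncertainties

Default history counts are desk-scale choices: 10⁷ for the single-seed
benchmark (≈1% on Λ, ≤2% on g(r) to 5 cm), 0.6–1.2 × 10⁷ per treatment
scenario (≈0.7% at the sclera, ≈1–2% at the apex and lens, ≈3% at the
weakest points), batches of 20–25 for error estimation. Systematic
uncertainty is dominated by the generated interaction data (~1% water/air,
a few % for gold) and, for absolute point doses, by the seed-layout and
point-of-interest placement conventions described above.

## What the synthetic scenes do not capture

The phantom is a stylized concentric-shell eye with a single tumor geometry;
real anatomies, plaque placements and notched/offset plaques are out of
scope, as are other plaque sizes, other seed models, electron transport,
microdosimetric GNP effects (particle size, intracellular localization —
the homogeneous-mixture model makes the 50 nm particle size irrelevant by
construction), and any radiobiology. Passing benchmarks here demonstrates
the transport, data and tally machinery on the stylized geometry, not
clinical accuracy for a particular patient.

## Numerical details

Boundary crossings restart the free-path sampling (surface tracking) with a
10⁻⁷ cm nudge past each surface; points exactly on a boundary resolve to the
cell the direction vector enters. Interpolation of interaction coefficients
is log-log between table nodes (exact at nodes); material grids are the
union of their elements' grids with edge-pair knots. Lost particles (a
geometry leak, never observed in the shipped scenes) and non-finite scores
abort or are reported in the run manifest. Degenerate inputs — zero-height
tumor (no-op), apex heights outside 0.25–1 cm, overlapping seed slots,
non-positive densities, fraction sums away from 1/100, energies outside
1–100 keV — raise immediately.
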
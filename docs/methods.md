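# Methods

## Scope and data flow

The package analyses a one-factor microcosm experiment: five stocking
ratios of *Ruditapes decussatus* (Rd) to *R. philippinarum* (Rp) —
8:0, 6:2, 4:4, 2:6, 0:8 — with five replicates each, plus five
unstocked controls (30 aquaria). Nutrients are sampled on days
0, 2, 5, 8, 12, 16 and 21; profile images are analysed at day 21.
The stages are: synthetic experiment generation → image quantification
→ mixed-depth metrics → permutation inference → report.

## Synthetic microcosm model

**Particle depths.** Each aquarium receives `n_particles` (default 400)
tracer particles. A particle stays in the surface carpet (depth 0) with
probability `surface_fraction`, otherwise its depth is exponential with
scale `mixing_scale_mm`, truncated at the species' burial bound:
120 mm when Rd is present, 80 mm for Rp-only aquaria. Controls use
`surface_fraction = 1` (the carpet is never remobilised); stocked
aquaria use 0 (all tracer is reworked). The exponential is the simplest
monotone mixing profile and keeps the truth metrics analytically
checkable: the truncated-exponential mean is
`s − T·e^(−T/s)/(1 − e^(−T/s))` for scale `s` and bound `T`.
The four tracer additions of the emulated protocol (days 0/4/11/17) are
pooled into one analysis-day population, since only day-21 images are
analysed.

**Between-replicate variability.** Each stocked aquarium draws its
mixing scale from N(treatment mean, 2.0 mm) (floored at 0.5 mm) and its
interface-roughness target from N(treatment mean, 4.0 mm) (floored
at 0). Default treatment means are calibrated to the reported day-21
group statistics: mixing scales 5.9, 7.3, 8.6, 10.0, 8.0 mm and SBR
targets 10, 7, 10, 13, 11 mm for 8:0 … 0:8 (the mixed-ratio aquaria mix
deeper than the monospecific ones). Controls use an SBR target of
0.5 ± 0.25 mm — almost flat, since nothing disturbs the surface.

**Interface and rendering.** The interface trace is smoothed Gaussian
noise (σ = 25 columns) rescaled so the integer-pixel peak-to-trough span
matches the SBR target to the nearest pixel. Frames are painted water /
sediment / pink luminophore discs (radius 1 px) centred
`depth/resolution` rows below the local interface row; optional additive
Gaussian pixel noise. Two raster presets exist: the full capture
geometry (0.07 mm/px, 1968 px wide) and a coarser `desk_scale` preset
(0.25 mm/px, 480 px wide) used by the simulation studies and tests;
recovery tolerances are expressed in physical units so they track the
raster choice.

**Nutrients.** Concentrations follow a linear trend between day-0 and
day-21 endpoints plus Gaussian noise truncated at 0 (no published error
model exists for single water samples; defaults NH₄-N σ = 1.0,
NOₓ-N σ = 0.15, PO₄-P σ = 0.05 mg L⁻¹). Default endpoints are the
reported series: control PO₄-P 0.10 → 0.32, control NOₓ-N 0.17 → 1.42,
control NH₄-N peaking at 3.56 mg L⁻¹; stocked NH₄-N endpoints run from
11.18 (8:0) to 9.24 (0:8) with intermediate ratios interpolated
linearly (only the monospecific endpoints are reported); stocked NOₓ-N
is flat at 0.45 mg L⁻¹ (reported as trendless, range 0.34–1.42); stocked
PO₄-P endpoints 0.72, 0.55, 0.49, 0.42, 0.49 mg L⁻¹. NH₄-N initials are
set to 0.5 mg L⁻¹ for all groups, above field levels, as expected in a
closed microcosm shortly after setup.

**Headline calibration.** `headline_calibration()` returns the same
generator with all stocked treatments sharing one mixing scale, one SBR
target and one endpoint per nutrient (each the across-ratio mean of the
defaults). Under it the between-ratio comparisons are true nulls while
the control still differs sharply — the configuration used to study the
experiment's headline significance pattern. With the per-ratio default
endpoints this pattern is not attainable for PO₄-P: the spread between
stocked endpoints (0.42–0.72) exceeds their distance to the control
(0.10), so no noise level makes the ratio test null while all control
contrasts reject; the shared-endpoint calibration is the cleanest
formulation of "ratios do not differ, controls do".

## Image quantification

**Segmentation** is a pink-dominance rule: R ≥ 120, R−G ≥ 60,
R−B ≥ 30 (configurable). The margins sit far above the default pixel
noise, so segmentation on rendered imagery is exact.

**Interface detection.** Water is the unique blue-dominant phase
(B > R and B > G); everything else is "solid". Per column, the
elevation is the topmost row from which a vertical window (default
5 rows) is at least `occupancy` solid — in treatment mode solid includes
luminophores (sediment–water interface), in control mode luminophore
pixels are excluded, so the trace falls *below* the unmixed carpet.
The default occupancy is 1.0 (the window must be fully solid): a
partial-occupancy majority rule would trigger inside the carpet —
within 2 rows of sediment in a 5-row window — placing the control
interface above carpet pixels and producing spuriously positive control
depths; full occupancy yields the sediment/carpet boundary exactly and
still resists isolated particles floating in the water column (they
cannot fill a window). A column in which no window qualifies aborts the
image — partial frames signal data problems rather than being skipped.

**Depth profile.** Each luminophore pixel contributes
`max(0, row − elevation(column)) × resolution` mm; pixels above the
interface clip to depth 0, so the control carpet carries a defined
depth-0 mass and control medians are well defined (and zero). Profile
mass always equals the segmented pixel count.

## Metrics

L_max, L_med, L_mean are the maximum, median and mean of the image-wide
pixel-weighted depth distribution (not per-column statistics averaged —
the image-wide form is the natural reading of a mixed depth of particle
redistribution). Even-count medians use midpoint interpolation. SBR is
(max − min) elevation × resolution, defined only for treatment-mode
traces; requesting it for a control trace is an error, and control rows
carry an empty SBR cell. Expected recovery bias is bounded by the disc
radius: measured depths differ from particle-centre truth by at most
the radius plus one pixel of quantisation, which is why the recovery
tolerance is stated as 2 × radius (mm) + 1 px.

## Permutation inference

One-way PERMANOVA partitions squared Euclidean distances (see README
for the formulas). Univariate responses are analysed one at a time
through the same distance machinery (Euclidean on log(X+1) scalars),
where the pseudo-F provably equals the classical one-way ANOVA F — the
test suite checks agreement to 10 significant digits against an
independent oracle.

Numerical and procedural choices:

* The permutation distribution is evaluated through SS_W only (SS_T is
  permutation-invariant and F is monotone decreasing in SS_W), which
  handles the SS_W = 0 / infinite-F case uniformly.
* Exhaustive enumeration over all distinct relabellings auto-activates
  when their count is ≤ the requested permutation number; the exact p
  counts the observed assignment once, with no +1 correction. A 5-vs-5
  contrast has 252 distinct assignments, so its minimum p is
  2/252 ≈ 0.0079.
* Monte-Carlo p-values use the (1 + count)/(1 + B) estimator with B
  unrestricted random relabellings (default 9999); permuted statistics
  tying the observed one (relative tolerance 1e-12) count toward p.
  The seed is a required, recorded input.
* All-zero distance matrices are an error (no variance to test);
  degenerate responses inside the pipeline surface as per-test error
  entries rather than aborting the whole report.
* Pairwise contrasts restrict the distance matrix to the two groups and
  report t = √pseudo-F, unadjusted for multiplicity (a Bonferroni
  correction can be applied downstream; none is applied by default).
* PCA is an eigendecomposition of the correlation matrix by default
  (the three nutrients share units but differ ~30-fold in scale);
  covariance form is available. Axis signs are fixed by making each
  axis' dominant loading positive.

## Analysis layout

Bioturbation responses: L_max, L_med, L_mean each get one main test
over the five stocked ratios (control excluded) plus five separate
control-vs-ratio contrasts; SBR gets the main test only (controls have
no SBR). Nutrients at day 21: three main tests plus five contrasts
each. The PCA ordinates the 6 × 7 = 42 per-treatment-per-day mean
nutrient vectors. Significance is flagged at p < 0.05; raw p-values are
always reported, and provenance (seed, permutation count, config hash,
version) is embedded in every report.

## Problem sizes and runtime

Simulation studies run at the `desk_scale` raster with 400 particles
and 30 aquaria per experiment; the null-calibration study uses 1000
datasets of 6 groups × 5 replicates at 999 permutations; the
headline-pattern study uses 20 independent experiments at 9999
permutations. The full test suite runs in about a minute,
`scripts/acceptance.py` in about one minute.

## What the simulations do and do not show

Passing recovery and pattern checks demonstrate that the pipeline
measures what the generator encodes: known particle depths, a known
interface span, known group structure. Real imagery adds phenomena the
generator omits — uneven illumination, colour bleed and JPEG artefacts,
partially buried/occluded particles, wall effects at the aquarium face,
non-exponential mixing profiles (e.g. bimodal burrow-depth layers), and
temporal correlation between tracer additions. Segmentation thresholds
and the interface window are therefore configurable, and conclusions
about real sediments require validation against hand-annotated frames.

## Known limitations

* The particle-depth law is phenomenological; no mechanistic transport
  (biodiffusion) coefficient is estimated.
* The asymptotic "Monte-Carlo P" of some commercial PERMANOVA
  implementations (a separate approximation distinct from the
  permutation p) is intentionally not provided.
* Time-lapse analysis across days, multi-colour tracer discrimination
  and camera calibration are out of scope.
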
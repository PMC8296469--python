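# Methods

## Gamma evaluation

The gamma index combines a dose-difference criterion with a
distance-to-agreement (DTA) criterion. This implementation is *global*: the
dose tolerance is `dose_diff_pct` (default 3%) of the maximum of the
reference grid over the whole grid, matching the usual reading of "global
gamma with suppression below 10% of the maximum dose". Suppression removes
voxels from the analysis entirely — they appear neither in the numerator nor
the denominator of the passing rate. Per-ROI normalization exists as a
non-default option (`local_normalization`).

Numerical choices, all recorded in `GammaCriteria` so the brute-force oracle
can replay them exactly:

* Candidate positions form a cubic lattice of step `dta_mm / 10` centered on
  the scored voxel, truncated to a sphere of radius `search_cap_mm`
  (default 3 × DTA). The evaluated dose is trilinearly interpolated;
  lattice points outside the voxel-center hull are skipped (no
  extrapolation). The 1/10-DTA step bounds the discretization error of
  gamma near the pass/fail boundary; the cap bounds cost, and a voxel whose
  true optimum lies beyond it reports the in-cap minimum
  (≥ `search_cap_mm / dta_mm`).
* A voxel passes at γ ≤ 1 exactly; a 1e-9 guard absorbs floating-point
  round-off on constructions that sit exactly on the boundary (e.g. a
  uniformly scaled evaluated dose at the dose criterion).
* The production search visits offsets in ascending distance and stops when
  the pure distance term can no longer beat the running minimum; this bound
  is exact because the dose term is non-negative, so pruning changes no
  value. The exhaustive oracle (`gamma_bruteforce`, ≤ 32³ voxels) visits
  every lattice point with independently written interpolation arithmetic;
  the suite requires agreement to 1e-9.
* Both grids must share an identical header. No resampling happens anywhere
  in the package: comparing grids on different frames is an upstream,
  explicit decision, because silent resampling would alter gamma.

The reference and evaluated roles are not interchangeable (the search runs
over the evaluated distribution); the suite asserts this asymmetry.

## DVH conventions

* `Dmax` is the single-voxel maximum. Near-max statistics (e.g. D(1%)) are
  available through `d_levels` and are preferable for serial organs, but the
  reported headline value stays the reproducible voxel maximum.
* `V(x)` counts voxels with dose ≥ x (closed at the level); `D(p%)` is the
  dose of the k-th hottest voxel, k = ceil(p/100 · n), clamped to ≥ 1.
* Constraint checks are strictly `<`; equality fails.
* The relative mean-dose difference is signed:
  `100 × (Dmean_eval − Dmean_ref) / Dmean_ref`, negative when the evaluated
  engine underestimates.

Volumes (V_air, V_bone) are reported from the voxelized masks, not polygon
integration, so the (volume, passing-rate) pairs entering the regression
refer to exactly the voxel sets the gamma evaluation scored. Rasterization
uses voxel-center inclusion under the even-odd rule (points on an edge count
inside); polygons mapping to one grid slice combine by XOR so inner contours
act as holes.

## Cohort statistics

The passing-rate/volume relationship is modeled as γ = a + b ln V by
unweighted ordinary least squares; R² = 1 − SS_res/SS_tot. A response with
zero variance yields the flat line b = 0 with R² defined as 0. The
95%-crossing volume is V* = exp((95 − a)/b); for b > 0 plans fail below V*,
for b < 0 above it. Paired comparisons use the two-sided paired Student
t-test with n−1 degrees of freedom; zero-variance differences are reported
as (t = ±∞, p = 0) or (t = 0, p = 1) rather than NaN. Significance at
p < 0.05 is reported as a flag, never used as a filter.

## Synthetic phantom cohorts

The generator emulates a 40-case head-and-neck QA study: an ellipsoidal
target (default semi-axes 60 × 55 × 45 mm on a 64³ grid at 2.5 mm, the
common clinical dose-grid spacing) containing one air cavity and one bony
structure. Structure volumes follow lognormal laws moment-matched to
36.7 ± 36.1 cc (air) and 41.2 ± 37.9 cc (bone). Draws above 140 cc are
redrawn, as are joint draws whose combined equivalent radii could not be
placed disjointly inside the target; the two structures are assigned
antipodal sides of the target's long axis with seeded jitter, and realized
voxel volumes are tuned to within 5% of the request.

The "planned" dose is the prescription (70.4 Gy) times a Gaussian-smoothed
target indicator (σ = 5 mm) — a deliberate simplification with no beam
geometry, chosen so the target interior (including both heterogeneities)
sits on a flat dose plateau with a penumbra-like falloff. The reference
("MC") dose adds i.i.d. Gaussian noise with SD equal to `mc_noise_frac`
(default 0.5%, alternative 2%) of the maximum dose. The evaluated ("TPS")
dose is the planned dose times (1 + f), where f sums three seeded fields:

* **Air interface deficit.** A depth-graded dose deficit over the cavity:
  weak on the outermost voxel layer (ratio 1/6), full strength on the
  deeper shell layers (up to 5 mm), mild over the core (ratio 0.15). The
  amplitude scales as (V/40 cc)^(−1/3), so small cavities carry per-voxel
  errors far beyond the 3% criterion while large cavities drop below it —
  the passing rate rises with ln V_air.
* **Bone surplus.** A dose surplus over the whole bony structure scaling as
  (V/40 cc)^0.3, modulated by a smooth zero-mean texture field (±100%,
  correlation 7.5 mm), so the fraction of bone voxels beyond the criterion
  grows with volume — the passing rate falls with ln V_bone.
* **Background.** A smooth multiplicative discrepancy field everywhere
  (SD 0.3% of local dose, correlation 25 mm), standing in for broad
  engine-to-engine differences.

Heterogeneity error amplitudes are expressed relative to the *maximum* dose
(the gamma criterion's own normalization), so a structure's failing fraction
does not depend on where in the plateau it was placed.

This voxel-level mechanism is an invention — real engines' interface errors
are not published per voxel — and only its cohort-level consequences are
calibrated. A one-time fixed-seed calibration run set the two amplitude
constants per engine model so the cohort-mean relative mean-dose differences
land at the emulated targets: −1.6% (air) and +2.3% (bone) for the
"AAA-like" model, −0.2% and +0.4% for the "AXB-like" model. The calibrated
constants live in the `aaa_like()` / `axb_like()` factory functions, not in
the dose-construction code. With these settings the synthetic cohort
reproduces the qualitative laws the pipeline is built to detect — passing
rate proportional to ln V_air and inversely proportional to ln V_bone for
the error-prone engine, no volume dependence for the accurate engine, and a
strict drop in interface passing rates when the reference noise rises from
0.5% to 2% — while the *absolute* passing-rate levels are a consequence of
the mechanism, not a calibration target.

Seeding: one master seed; case i derives placement and dose-field seeds via
`SeedSequence(master, spawn_key=(i, stream))`, and the dose synthesis
derives noise/texture/background streams the same way, so any single case
or field is reproducible in isolation and different engine models share
identical random-field realizations (only amplitudes differ).

`generator_implied_crossing` defines the yardstick for the recovered
95%-crossing volume: the median crossing over independent replicate cohorts
(same sampling law and case count, derived seeds). The replicate median
absorbs the sampling variability of the crossing estimator itself, so a
test cohort's recovered crossing is compared against what the generator
actually implies for that estimator.

What the synthetic cohort does *not* emulate: beam/MLC geometry, CT-derived
densities, realistic OAR anatomy, multi-structure targets, or spatially
correlated MC noise. Passing the synthetic checks therefore demonstrates
that the pipeline's measurement chain (masking, gamma, DVH, regression) is
correct and sensitive to volume-dependent interface errors; it does not
validate any physical claim about a specific commercial engine.

## Problem sizes

Default analyses run 40 cases on 64³ grids at 2.5 mm; the gamma oracle
equivalence checks use 16³ grids (the exhaustive search is O(voxels ×
lattice points)); DVH oracles use 6³ masked grids. These sizes keep the full
suite and the acceptance script each within a few minutes on one CPU while
leaving every statistical check comfortably powered.

## Known limitations

* Only axis-aligned, uniformly spaced grids; oblique DICOM geometry is a
  hard error.
* The gamma search interpolates trilinearly only; no higher-order schemes.
* Single air cavity and single bony structure per phantom, while real
  targets contain many; the cohort-level statistics, not per-case anatomy,
  are the emulation target.
* The paired t-test applies no multiple-testing correction across
  structures (reported p-values are per-structure).
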
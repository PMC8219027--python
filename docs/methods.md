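# Methods

This note documents the models implemented in `rad51quant`, the default
parameters and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical and design choices a maintainer
should know about.

## Equilibrium binding models

### Two-state quadratic

`direct_bound(P_t, L_t, K_L)` returns the physical (smaller) root of the
mass-action quadratic for P + L ⇌ PL. It is used both directly (probe
saturation at assay conditions) and as the I_t → 0 / K_I → ∞ limit that the
competition model must reproduce exactly.

### Exact ternary competition

`wang_competitive_bound` solves the simultaneous equilibria of a protein
shared between a labelled probe and a competitor without any approximation
(no IC50-to-Ki conversion): free protein is the unique root in
[0, P_t] of the cubic stated in the README. Numerics:

* the trigonometric closed form is evaluated first (vectorized over the
  competitor concentrations), with the arccos argument clipped to [−1, 1];
* four Newton iterations polish the root — the closed form alone loses up
  to ~6 digits at extreme concentration ratios (e.g. P_t/K_I ≈ 10⁸);
* any point whose mass-balance residual still exceeds 10⁻⁹ (relative to
  P_t) is re-solved with a bracketed Brent root on the untransformed mass
  balance. In practice this path triggers only in degenerate corners, but
  it makes the guarantee unconditional.

The unit tests and the acceptance suite compare against an independent
bracketed solve of the raw mass balance on random parameter grids spanning
10⁻¹⁰–10⁻² M; observed agreement is ~10⁻¹⁴ relative, far inside the 10⁻⁸
requirement.

### FP signal model and fitting

Polarization readings are modelled as affine in the bound fraction
(`fp_signal`), with the two plateaus as free parameters. Whether the
instrument reports polarization or anisotropy units does not matter for an
affine model; nothing in the fit depends on the absolute scale.

`fit_competition_isotherm` does nonlinear least squares over
(pKd, plateau_bound, plateau_free) with the probe K_L *fixed* at its
independently measured value (default 4 nM, the FP-measured estimate for
this system; configurable through `AssayConstants`). Parameterizing in pKd
rather than Kd makes the error model symmetric on the log scale, which is
also the scale on which replicate estimates are averaged
(`pkd_statistics`: geometric-mean Kd, SD in log10 units). Plateaus are
fitted with wide bounds rather than pinned to control wells, since plateau
handling is an assay-plate detail the model should not hard-code; each
isotherm gets its own plateaus. Replicate wells are fitted as pooled
points; `average_isotherms` implements the replicate-averaging workflow
(average within plate, then across independent isotherms) when that is the
desired preprocessing.

Diagnostics: non-convergence is flagged, and a curve whose fitted
transition amplitude is indistinguishable from the residual noise is
flagged `no_transition_unbounded_pkd` instead of reporting a meaningless
affinity.

Calibration (Monte-Carlo, in the test suite): with 5 mP noise on 10-point
single-replicate curves the median |pKd error| is ≈ 0.04 log units, and
the covariance-derived pKd SD tracks the empirical scatter within a factor
of two.

### ITC single-site model

`itc_heats` implements the 1:1 Wiseman isotherm with constant-volume
displacement bookkeeping: each injection of volume v first dilutes both
cell species by (1 − v/V₀) (the displaced volume leaves the cell carrying
pre-injection concentrations), then adds syringe ligand, then the bound
concentration is recomputed from the quadratic with n·M binding sites. The
measured heat of injection i is ΔH·V₀·(B_i − B_{i−1}(1 − v_i/V₀)). Summed
over a saturating titration this conserves ΔH·n·(moles of cell species) up
to the few percent of sites lost in displaced volume — the conservation
test therefore uses small injections (12 × 1 µL into 200 µL) and a 5%
tolerance.

`fit_itc` fits (log₁₀Kd, ΔH, n) by least squares; `fix_n` holds the
stoichiometry, the standard practice for weak binders where n and ΔH are
nearly collinear — the test suite verifies that fixing n = 1 reduces the
across-seed variance of the recovered Kd for a binder with Kd ten times
the cell concentration. Injection order matters physically, so an
`InjectionSchedule` carrying out-of-order injection numbers is rejected at
construction.

Defaults mirror a typical small-molecule titration on a 200 µL
microcalorimeter cell: 20 µM protein in the cell, a 10-fold excess of
ligand in the syringe, 19 × 2 µL injections, ΔH of order −40 kJ/mol.

## SMLM cluster pipeline

Stage order and thresholds (all in `FilterConfig`, defaults exactly the
published analysis values):

1. photons ≥ 1,000 and precision ≤ 20 nm. **Direction note:** the filter
   discards localizations whose precision value is *larger* (worse) than
   20 nm. Reading the threshold in the opposite direction would discard
   the best-localized detections; the cut is configurable.
2. Voronoi density ≥ 5×10⁻⁵ nm⁻² (cell area ≤ 2×10⁴ nm²). The
   tessellation is recomputed on this stage's input only, matching the
   sequential narrative of the analysis; unbounded boundary cells have
   zero density and are always removed. Fewer than 4 points or collinear
   input have no 2-D tessellation: the stage warns and returns empty.
3. at least 20 *other* detections within 100 nm (inclusive radius, self
   excluded). No edge correction is applied; fields are large relative to
   clusters, so boundary under-counting is negligible at the default
   geometry.
4. Delaunay triangulation; edges strictly longer than 20 nm are cut;
   connected components with ≥ 3 members are the clusters. Components of
   the thresholded Delaunay graph equal components of the full
   distance-threshold graph (the triangulation contains the Euclidean
   minimum spanning tree), which is how the test oracles verify the
   partition independently.
5. molecules per cluster = localization count / ε, kept real-valued for
   statistics with a rounded display value floored at 1.

Tie-break conventions mirror the stated wording: "fewer than 1,000" keeps
exactly 1,000; "less than 20 neighbours at ≤ 100 nm" keeps a neighbour at
exactly 100 nm; "larger than 20 nm" keeps an edge of exactly 20 nm;
"less than 3 localizations" keeps a 3-member component.

### Antibody calibration

`calibrate_epsilon` processes a sparse single-antibody field with the same
photon/precision filter and the same Delaunay segmentation (edge cut and
minimum size) as the main pipeline, and takes ε as the **median** cluster
size (robust against the heavy right tail of blinking counts; the mean is
available). The density and neighbour filters are *not* applied to the
calibration field: they are designed for crowded damage-site fields, and an
isolated antibody producing a dozen localizations can never accumulate 20
neighbours — applying them would reject every calibration cluster.

### Known biases of the counting rule

Two systematic effects, both reproduced and quantified by the synthetic
tests rather than hidden:

* **Peripheral erosion.** The Voronoi density filter removes the outermost
  localizations of every cluster (their cells extend into empty space), so
  full-pipeline counts are biased a little low relative to planted truth.
  The counting arithmetic itself is exact: segmenting an unfiltered,
  dispersion-free field recovers every planted count perfectly.
* **Blinking dispersion.** With geometric blinking, per-cluster counts
  inherit a heavy-tailed variance, and the median-based ε is not the mean
  of the blinking distribution. Across seeds the pipeline still recovers
  the planted cluster number exactly and per-cluster molecule counts with
  a median absolute error below 2 molecules at the 5–10-molecule scale.

### Shape metrics and group comparison

`cluster_metrics` reports the centroid, localization count, principal-axis
extent (range of projections on the leading eigenvector of the scatter
matrix), anisotropy (major/minor axis SD ratio; infinite for collinear
clusters) and an `extended` flag at extent > 200 nm — the scale separating
early molecular clusters from assembled filaments.

`compare_groups` runs the tie-corrected Kruskal–Wallis H test across
groups of per-cluster molecule counts, then pairwise comparisons on group
mean ranks with Tukey–Kramer familywise adjustment: the statistic
|ΔR̄| / √(S²/2·(1/nₐ + 1/n_b)) is referred to the studentized-range
distribution with k groups and infinite degrees of freedom, S² being the
tie-corrected pooled rank variance N(N+1)/12·(1 − Σ(t³−t)/(N³−N)). This is
the behaviour of the common post-Kruskal–Wallis multiple-comparison
routines. An all-identical input makes H undefined; the report says so
instead of raising. Box-plot summaries (median, quartiles, 1.5·IQR
whiskers, mean) accompany the test.

## Dose–response

The 4PL model is fitted on log₁₀ dose with plateau bounds [−10, 110] % and
hill-slope bounds [0.2, 5] — both stabilize the sparse 8–10-point curves
typical of plate assays; the slope is assumed variable (not fixed at 1).
Replicates are fitted as pooled points by default. The midpoint SE comes
from the fit covariance via the delta method (no bootstrap). A midpoint
outside the measured dose range is flagged `extrapolated_midpoint`; an arm
whose fitted amplitude is below max(3·residual SD, 5 percentage points) is
flagged flat and excluded from combination fold-shifts.

`combination_table` fits each arm of a shared-grid design and reports
fold-shift = midpoint(reference)/midpoint(arm), so values above 1 mean the
combination sensitizes. The reference defaults to the first arm
(conventionally the vehicle / 0-Gy arm).

## Synthetic-data generators

Each generator is the exact forward model of its fitter; with zero noise
the corresponding fit recovers the generating parameters to numerical
tolerance, and all randomness flows through a single `default_rng(seed)`.

The localization generator emulates the statistical structure of a d-STORM
localization table, not the microscopy: clusters of labelled molecules
(uniform discs or straight filaments with Gaussian transverse jitter and
uniform orientation), a geometric number of localizations per molecule
(blinking re-activation treated as memoryless; the antibody-labelling
stoichiometry distribution is not experimentally characterized, so this is
an explicit stand-in, configurable), per-detection lognormal photon counts
and truncated-Gaussian precisions, position jitter equal to each
detection's own precision, and spatially uniform background. It does not
model raw frames, PSFs, temporal blinking kinetics, drift, or repeated
localization correlations beyond the per-molecule count — so passing
recovery tests demonstrate the pipeline's geometry and bookkeeping, not
robustness to instrument artefacts.

Default study conditions:

| parameter | default | rationale |
|---|---|---|
| field | 256 × 256 px at 160 nm | acquisition geometry of the emulated experiment |
| clusters per field | 10, ≥ 500 nm apart, margin from edges | unambiguous planted truth |
| molecules per cluster | uniform 5–10 | the reported scale of damage-induced RAD51 nanoclusters |
| disc radius | 25 nm | a 5–10-molecule nucleoprotein cluster is tens of nm across; after antibody displacement and ~10 nm precision blur it appears ~70–90 nm, clearly below the >200 nm filament scale |
| filament length/width | 400 / 30 nm | extended damage-site filaments; width read as full transverse width (≈ ±2σ) |
| localizations per antibody (ε_true) | 15, geometric | a dye-conjugated secondary antibody carries several fluorophores and yields on the order of 10–30 localizations over a 25,000-frame acquisition; also the regime in which the pipeline's own ≥ 20-neighbour rule leaves genuine 5-molecule clusters detectable |
| photons | lognormal, median 2,000, σ_log 0.5 | typical d-STORM statistics; a tunable fraction (~8%) falls under the 1,000-photon cut so the filter is exercised |
| precision | Gaussian 10 ± 3 nm, truncated at 2 nm | typical d-STORM precision; a small tail exceeds the 20 nm cut |
| background | 10⁻⁶ nm⁻² | sparse nonspecific labelling, ~1,700 detections per field |

For filament fixtures the tests use 30–50 molecules per filament (about
one labelled molecule per 10 nm of filament), reflecting the much higher
molecule content of an assembled filament compared with an early cluster.

FP plates default to the assay constants (50 nM protein, 10 nM probe,
K_L 4 nM), plateaus 200/50 signal units, 5-unit Gaussian well noise, two
replicates per plate. Dose–response fixtures default to triplicate wells,
the usual growth-assay plate design.

## Problem sizes in the tests

The test suite runs entirely on synthetic data generated at call time:
random-grid model comparisons use 10³–10⁵ parameter draws; brute-force
SMLM oracles run on single fields of ~10³ localizations; recovery studies
use 20 seeds × 10 clusters (discs) and 10 seeds × 6 filaments; Monte-Carlo
fit calibrations use 60–100 seeds. These sizes give stable medians and
keep the whole suite around half a minute.

## Known limitations

* The counting biases described above (peripheral erosion, blinking
  dispersion) are inherent to the sequential-filter counting rule; the
  package reports real-valued counts so downstream statistics can handle
  them honestly.
* No instrument file formats (Origin/Microcal, raw ThunderSTORM protocol
  variants beyond the simple column mapping), no competitive ITC, no
  Bliss/Loewe synergy scoring, no 3-D localization support.
* Concentration grids are treated as exact (no x-error model), and FP
  readings are assumed affine in the bound fraction.
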
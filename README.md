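# rad51quant

Quantitative analysis for studies of small-molecule inhibitors of the
BRCA2–RAD51 protein–protein interaction. The package bundles, as tested
reusable code, the four analyses such a study runs on its raw data:

1. **Competitive fluorescence-polarization (FP) binding** — exact
   closed-form ternary equilibrium (protein + labelled probe + competitor),
   nonlinear pKd fitting, and geometric-mean replicate statistics.
2. **Isothermal titration calorimetry (ITC)** — the 1:1 single-site
   Wiseman isotherm with displacement-volume dilution bookkeeping, and
   least-squares recovery of (Kd, ΔH, n).
3. **d-STORM cluster quantification** — the sequential single-molecule
   localization pipeline: photon/precision filtering, Voronoi-density
   filtering, neighbour-count filtering, Delaunay edge-cut segmentation,
   antibody-calibrated molecule counting, cluster/filament shape metrics,
   and Kruskal–Wallis/Tukey–Kramer group comparison.
4. **Dose–response analysis** — percent inhibition, fold change, 4PL
   (IC50/GI50) fitting on log dose, and fixed-dose combination tables
   (e.g. drug titrations at several ionizing-radiation doses).

A synthetic-data module generates every input the pipeline consumes —
localization fields with planted ground truth, FP plates, ITC thermograms,
dose–response tables — as the exact forward model of the corresponding
fitter, so parameter recovery is testable end to end.

## The models

**Two-state probe binding.** For protein and probe totals $P_t, L_t$ and
probe dissociation constant $K_L$, the bound complex is the physical root of

$$[PL]^2 - (P_t + L_t + K_L)[PL] + P_t L_t = 0 .$$

At the assay conditions (50 nM protein, 10 nM probe, $K_L$ = 4–6 nM) this
gives 87–91% of the probe bound.

**Exact competition.** With a competitor at total $I_t$ and constant
$K_I$, the free protein concentration $[P]$ is the unique physical root of
the mass-action cubic

$$[P]^3 + a[P]^2 + b[P] + c = 0,\quad
a = K_L + K_I + L_t + I_t - P_t,\;
b = K_I(L_t{-}P_t) + K_L(I_t{-}P_t) + K_LK_I,\;
c = -K_LK_IP_t,$$

solved in trigonometric closed form with Newton polishing (bracketed
fallback when the closed form is marginal); the probe-bound fraction is
$[P]/(K_L + [P])$. Fits are parameterized in pKd $= -\log_{10} K_I$ so
uncertainties are symmetric on the log scale, and replicate affinities are
summarized as the geometric mean of $K_d$.

**Molecule counting.** Clusters are connected components of Delaunay edges
≤ 20 nm among localizations that survive the photon (≥ 1,000), precision
(≤ 20 nm), Voronoi-density (≥ 5×10⁻⁵ nm⁻²) and neighbour (≥ 20 within
100 nm) filters; molecules per cluster = localizations / ε, with ε the
median localization count of isolated single antibodies processed the same
way.

## Worked example

```python
import numpy as np
import rad51quant as rq

# --- FP competition: simulate a noisy plate at pKd 6.45, refit it
assay = rq.AssayConstants()                    # 50 nM protein, 10 nM probe, Kd 4 nM
conc = np.geomspace(1e-8, 1e-3, 11)
iso = rq.simulate_fp_plate(assay, competitor_pkd=6.45, concentrations=conc,
                           noise_sd=5.0, n_replicates=2, seed=7)
fit = rq.fit_competition_isotherm(rq.average_isotherms(iso))
print(f"pKd = {fit.pkd:.3f} +/- {fit.pkd_sd:.3f}  (Kd = {fit.kd*1e9:.0f} nM)")
# pKd = 6.469 +/- 0.032  (Kd = 340 nM)

# --- SMLM: recover planted clusters and molecule counts
table, truth = rq.simulate_localizations(rq.ClusterSpec(), seed=0)
cal_table, _ = rq.simulate_localizations(
    rq.ClusterSpec(n_clusters=200, molecules_per_cluster_range=(1, 1),
                   background_density_per_nm2=0.0), seed=1)
cal = rq.calibrate_epsilon(cal_table)          # epsilon = 14.0
clusters, log = rq.run_pipeline(table, cal=cal)
print(log)
# {'input': 2776, 'photon_precision': 2542, 'voronoi_density': 885,
#  'neighbor_count': 885, 'clustered_localizations': 885, 'n_clusters': 10,
#  'epsilon': 14.0}
```

All 10 planted clusters are recovered; matching recovered clusters to the
planted ones by centroid gives per-cluster molecule estimates with a median
absolute error of 1.0 molecules for this seed (planted counts 5–9,
estimates e.g. 7 → 6.3, 9 → 9.2, 8 → 7.8). The stage log shows what each
filter removed: the Voronoi density cut eliminates nearly all the uniform
background, and the survivor counts shrink monotonically stage by stage.

The same workflow is scriptable from the shell:

```
rad51quant simulate --seed 0 --out fixtures/
rad51quant cluster run --input fixtures/localizations.tsv \
    --calibration fixtures/calibration.tsv --out results/
rad51quant fit-fp --input fixtures/fp_plate.csv
rad51quant run-all --seed 0 --out run/
```

Every run directory receives a JSON manifest (config snapshot, input
hashes, seeds, stage logs) sufficient to reproduce its outputs exactly.

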
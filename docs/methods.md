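# Methods

## Scope and design

`psmdnet` implements the analysis chain of a cross-sectional case-control
diffusion MRI study — skeletonized peak-width metrics, fiber-number
connectomes with global topology, and the linking statistics — together
with a synthetic-data tier that stands in for acquisition and
preprocessing. Registration, tensor fitting and brain extraction are out of
scope: all volumes are assumed to live in a common space, and the synthetic
generator produces them there directly. Real FSL/TBSS bit-parity is not a
goal; the skeletonization is validated instead by centerline recovery on
phantoms with known geometry.

## Synthetic phantoms and cohorts

A phantom is a set of tube-shaped tracts (parametric centerline, radius,
Gaussian or flat radial FA profile, core MD) in a ≥16³ voxel grid, plus
box/ellipsoid CSF regions of high MD (default 3×10⁻³ mm²/s), i.i.d.
Gaussian noise on FA (SD 0.02) and MD (SD 2×10⁻⁶ mm²/s), and a background
MD of 7×10⁻⁴ mm²/s. AD and RD are derived from (FA, MD) via the axially
symmetric tensor relation `δ = FA/√(3−2FA²)`, `AD = MD(1+2δ)`,
`RD = MD(1−δ)`, so the trace identity `MD = (AD+2RD)/3` and the ordering
`AD ≥ MD ≥ RD` hold exactly wherever FA > 0. The principal eigenvector is
the centerline tangent. The default phantom is a 6-node, 8-tube network
(two triangles sharing a hub plus a tail) in a 32³ grid of 2 mm voxels,
chosen so that clustering, hierarchy and assortativity are all defined on
the resulting connectome.

**MD heterogeneity (what PSMD measures).** Each subject carries a smooth
low-frequency MD offset along each tract: a random-phase harmonic field in
arclength (wavelength 4× the `perturb_corr_mm` knob, default 16 mm),
constant across each tract cross-section. The field is exactly zero-meaned
and rescaled so that its 95th−5th percentile width over one sample per
centerline voxel equals the subject's latent PSMD. Two consequences: the
subject's measured PSMD matches its latent value with ~1% accuracy without
any downstream adjustment (the bounded, arcsine-like marginal of a harmonic
field makes the extreme percentiles insensitive to how the skeleton
subsamples the tract — a Gaussian field's tails are not), and the
skeletonized *average* MD is unaffected, reproducing the width-vs-mean
dissociation that motivates the peak-width statistic. Because AD/RD are
derived from MD at fixed FA, the heterogeneity propagates into PSAD/PSRD;
the phantom dissociates PSMD from average MD, not from the other peak
widths.

**Group effects.** Latent subject metrics are drawn as
`PSMD ~ 1.67e-4 · exp(N(0, 0.07)) · psmd_effect^patient` and analogous
normal models for Eg (base 12.76, CV 0.143) and lambda (base 1.18, CV
0.042). The default multipliers (PSMD 1.76/1.67, Eg 12.07/12.76, lambda
1.20/1.18) and all score/covariate magnitudes are calibrated to a published
first-episode schizophrenia cohort of 56 patients and 64 controls; they are
fixed conditions of the simulation, not fitted values. At multiplier 1 the
groups are exchangeable by construction. Network effects reach the images
as *focal* tract damage: every tract's caliber gets lognormal
between-subject jitter (CV 0.12), and patient tracts are severely thinned
(×0.35) with probability `1 − eg_effect` per tract. A uniform caliber
change would cancel in the connectome weight normalization; focal
heterogeneity is what moves weighted efficiency, and it lowers measured Eg
as intended (verified directionally in tests). The generator also has a
volume-free tier (`make_volumes=False`) that emits only the latent metric
columns, covariates and scores; it is used for large-replicate statistical
simulations, and its consistency with the imaging tier rests on the exact
width normalization above.

**Clinical scores.** Scores are linear-Gaussian: mean + patient shift +
loadings on standardized latent metrics + covariate loadings + noise. The
reasoning/problem-solving score loads −0.426 (PSMD) and −0.490 (lambda)
standardized units with residual SD √(1−0.426²−0.490²); its patient
deficit arrives entirely through those loadings. The three PANSS scales are
patient-only, correlated through a shared factor (loading 0.774, inter-scale
r ≈ 0.6), with the total defined as their sum. Covariates: age, sex (0/1),
education (years), TIV (cm³), identically distributed in both groups.

## Skeletonization and projection

The skeleton is built from the cohort mean FA. For each candidate voxel
(mean FA ≥ 0.2), the perpendicular direction is the FA-weighted
center-of-gravity offset of the 3×3×3 neighborhood when its magnitude
exceeds 0.1 voxel, otherwise the axis/diagonal direction (of the 13) with
the most negative second derivative of mean FA (normalized by squared step
length; ties broken by a fixed direction order). A voxel is on the skeleton
iff its FA is ≥ both neighbors along that direction; exact FA ties keep the
lexicographically smaller coordinate, making the skeleton deterministic.
Projection searches ±8 voxels (configurable) along the stored perpendicular
for the subject's maximum FA, truncating at the volume boundary, and reads
MD/AD/RD at that same location (shared projection parameters). Ties prefer
the smaller offset, positive side first. The analysis mask keeps skeleton
voxels with template mean FA ≥ 0.3 outside an exclusion volume; in
synthetic runs the exclusion is the generated CSF regions dilated by one
voxel, in real runs any NIfTI mask. The skeletonized *averages* use the
same mask as the peak widths by default (recorded in provenance).

## Peak widths

`peak_width` is the difference of linear-interpolation ("type 7")
quantiles, default 5th/95th percentiles; the convention is recorded in the
report provenance. Metrics are stored in mm²/s and reported on the 10⁻⁴
mm²/s scale. Inputs with NaNs or fewer than two values are rejected.

## Tractography and connectome

FACT seeds one streamline per voxel center with FA ≥ 0.2 and tracks both
ways: within a voxel the path follows that voxel's eigenvector (sign-aligned
with travel) to the voxel boundary, then adopts the next voxel's vector.
Termination: next-voxel FA < 0.2, turning angle > 45°, or grid exit.
Streamlines shorter than three voxel diagonals (default) are discarded.
Axis ties at exact-diagonal boundary crossings resolve to the lowest axis,
keeping tracking deterministic. The connectome counts a streamline into
`W[i,j]` iff its two *endpoints* fall in distinct labeled regions
(pass-through counting is deliberately not the default; endpoints match
common deterministic-pipeline usage). Weights are symmetric integers with
zero diagonal.

## Graph metrics

Weights are normalized by the matrix maximum; edge lengths are reciprocal
normalized weights; shortest paths by Dijkstra. Global efficiency is the
mean inverse distance over ordered pairs (0 for disconnected pairs);
characteristic path length averages finite distances (largest component
when disconnected). Clustering is Onnela's geometric-triangle form; local
efficiency averages the efficiency of neighbor-induced subgraphs. γ and λ
divide clustering and path length by the means over 100 (default)
Maslov-Sneppen degree-preserving rewired graphs (10 swaps per edge) with
the original weights randomly permuted onto the rewired edges; σ = γ/λ.
When too few swappable edge pairs exist the partially rewired graph is
used. Assortativity is the Pearson correlation of endpoint strengths over
edges (undefined, by error, for regular graphs). Modularity is the maximum
Newman Q: exact exhaustive partition search for ≤8 nodes (Bell(8)=4140),
seeded Louvain restarts with greedy single-node/merge refinement beyond.
Hierarchy is β in `C ∝ k^(−β)` fitted by least squares over nodes with
degree > 1 and positive clustering (undefined for constant degree). On
degenerate subject connectomes the pipeline records NaN for the affected
metric rather than aborting, and the group statistics drop NaNs.

## Statistics

Normality is tested per group with the Lilliefors-corrected KS test
(plain KS against a fixed normal would be anti-conservative); groups
smaller than 4 are treated as normal, since the correction is undefined
there. Both groups normal → pooled-variance t (the classic single-df
convention; Welch is deliberately not the default); otherwise Mann-Whitney
U with tie-corrected normal-approximation Z and median (Q1, Q3) summaries.
Chi-square omits the continuity correction. ROC AUCs are rank statistics
with half-credit ties; variance, 95% CI and the test against chance use
DeLong placements, and scores are inverted when needed to keep AUC ≥ 0.5
(flip flagged). The paired DeLong comparison errors on literally identical
score vectors; two different score vectors with identical placements (a
monotone transform) yield p = 1. Partial correlation residualizes both
variables on the covariates plus intercept and tests r with df = n−2−k.
Hierarchical regression fits covariates first, then covariates + metrics;
standardized β come from a z-scored refit, t/p from the raw full model,
VIFs from each predictor regressed on the others, and both the block-1 and
full R² are reported because the "model fit" of a hierarchical table can
refer to either (the full model is primary here). BH-FDR families are the
clinical scales within each metric for correlations, and the set of
dependent scales for regressions.

## Problem sizes and defaults

The shipped defaults favor interpretable, quick simulations: 32³ grids with
2 mm voxels, 6-node/8-tube networks, 100 nulls, 10 modularity restarts.
Test and acceptance simulations use 10-24-subject imaging cohorts, 16³
single-tract grids for 200-500-replicate null calibrations, and the
volume-free tier for 200-replicate pattern-recovery runs at the full 56/64
sample size.

## What passing tests do and do not show

The phantoms have no curvature-induced partial voluming, no crossing-fiber
ambiguity inside a voxel (the eigenvector field is single-valued), no
registration error, no motion or eddy artifacts, and their "anatomy" is a
toy network. Passing tests therefore validate the *computations* — the
skeleton search finds ridges, the projection carries displaced values, the
peak width equals its definition, FACT obeys its termination contract, the
graph metrics equal brute-force enumeration, the statistics are calibrated
— not the biological validity of PSMD or the behavior of the chain under
real-scanner artifacts. Reported group means match their calibration
targets because the generator is calibrated to them; they are demonstration
conditions, not discoveries.

## Known limitations

* Skeletonized averages over the masked skeleton are one of two defensible
  mask choices; the unmasked-skeleton variant is available via
  `fa_threshold=0` with no exclusion.
* The harmonic heterogeneity field has a two-point marginal at its extremes;
  it is a deliberately stable stand-in for pathology, not a model of it.
  Its spatial scale is a free knob (`perturb_corr_mm`).
* PSAD/PSRD inherit the patient MD-heterogeneity (AD/RD are tied to MD at
  fixed FA), so the phantom does not reproduce a null PSAD/PSRD contrast.
* Weighted Eg/Eloc are reported on the normalized-weight scale in [0, 1];
  raw fiber-number scaling (which yields values ≫ 1) cancels by design.
* Latent network metrics (Eg, lambda) drive the statistics tier directly;
  the imaging tier reproduces their directions qualitatively, not their
  magnitudes.
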
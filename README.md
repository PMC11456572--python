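# psmdnet

White-matter microstructure and network topology from diffusion-tensor
scalar maps, for case-control studies: skeletonized peak-width metrics
(PSMD and friends), deterministic FACT connectomes with global graph
metrics, and the covariate-adjusted statistical battery that links them to
clinical scores — all runnable end to end on synthetic phantom cohorts, so
every stage is testable without scanner data.

## Who this is for

Neuroimaging methodologists who want a transparent, fully seeded
reimplementation of the PSMD + connectome analysis chain: to study its
statistical behavior (calibration, power, effect-direction recovery), to
validate processing choices on phantoms with known ground truth, or to run
the same statistics on their own pre-registered FA/MD/AD/RD volumes.

## The metrics

**PSMD** (peak width of skeletonized mean diffusivity) summarizes the
spatial heterogeneity of MD over the white-matter skeleton:

```
PSMD = q95(MD_skel) − q5(MD_skel)
```

where `MD_skel` are the subject's MD values projected onto the cohort
mean-FA skeleton (TBSS-style: each skeleton voxel takes the subject value at
the maximum-FA location along the local perpendicular), masked at mean FA ≥
0.3 with a ventricle-adjacent exclusion mask. PSFA/PSAD/PSRD and the
skeletonized averages are computed from the same masked samples.

**Connectome topology**: streamlines are tracked with FACT (follow the
principal eigenvector voxel to voxel; stop at FA < 0.2, turning angle > 45°,
or the volume edge), counted into a region×region fiber-number matrix, and
summarized by eight global metrics — global/local efficiency, normalized
clustering γ and path length λ (versus degree-preserving rewired nulls),
small-worldness σ = γ/λ, assortativity, modularity, hierarchy.

**Statistics**: Lilliefors-gated pooled-t / Mann-Whitney group comparisons,
χ², ROC with DeLong confidence intervals and paired AUC comparisons,
partial correlations adjusted for age/sex/education/TIV, hierarchical
regression with VIFs, Benjamini-Hochberg FDR.

## Worked example

```python
from psmdnet import RunConfig, run_pipeline
from psmdnet.synthetic import CohortConfig

cfg = RunConfig(cohort=CohortConfig(n_patients=12, n_controls=12, seed=7),
                n_nulls=50, seed=7)
report = run_pipeline(cfg)
g = report.subject_metrics.groupby("group")["PSMD"].mean() * 1e4
print(g.round(3))
print(report.group_table.set_index("variable").loc["PSMD",
      ["test", "statistic", "p"]])
```

prints

```
group
control    1.621
patient    1.789
Name: PSMD, dtype: float64
test         pooled_t
statistic    3.183087
p              0.0043
Name: PSMD, dtype: object
```

— the simulated patients carry wider skeleton-MD distributions (mean PSMD
1.79 vs 1.62 ×10⁻⁴ mm²/s here), the pooled-variance t-test flags the
difference, and (in the full report) the skeletonized *average* MD does
not differ: the dissociation PSMD is designed to capture.

The same stages are available from the shell:

```bash
psmdnet simulate --outdir sim --n-patients 4 --n-controls 4 --seed 1
psmdnet skeletonize --fa sim/sub-000/FA.nii.gz --fa sim/sub-001/FA.nii.gz \
    --out-skeleton skel.nii.gz
psmdnet peakwidth --subject-dir sim/sub-000 --skeleton skel.json \
    --out metrics.tsv
psmdnet run-all --seed 7 --outdir report/
```

`analyze`-style use on real data expects volumes already registered to a
common space; no registration is performed here.

## Layout

| module | contents |
| --- | --- |
| `psmdnet.synthetic` | phantom/cohort generators, parcellation, score model |
| `psmdnet.skeleton` | mean-FA skeleton search, projection, analysis mask |
| `psmdnet.peakwidth` | peak widths and skeletonized averages |
| `psmdnet.tractography` | FACT tracking, fiber-number connectome |
| `psmdnet.graphmetrics` | the eight global topology metrics + null models |
| `psmdnet.stats` | group tests, ROC/DeLong, partial correlation, regression, FDR |
| `psmdnet.pipeline` / `psmdnet.cli` | orchestration, report tables, CLI |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
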
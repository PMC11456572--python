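"""End-to-end orchestration: simulate -> skeletonize -> peak width ->
track -> graph metrics -> statistics, as one seeded, configured run.

The report mirrors the shape of a case-control imaging study: a per-subject
metrics table (8 diffusion + 8 topology columns), a group-comparison table,
a ROC table with DeLong comparisons of PSMD against the discriminating
topology metrics, a covariate-adjusted partial-correlation table
(patients only, FDR per metric across the clinical scales), and a
hierarchical-regression table with one row per clinical scale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .graphmetrics import compute_topology
from .peakwidth import compute_subject_metrics
from .skeleton import build_skeleton, make_analysis_mask, mean_fa, project_to_skeleton
from .stats import (
    GroupTestResult,
    compare_groups,
    chi_square_2x2,
    delong_compare,
    fdr_bh,
    hierarchical_regression,
    partial_correlation,
    roc_auc,
)
from .synthetic import SCORE_NAMES, CohortConfig, exclusion_from_csf

logger = logging.getLogger("psmdnet")

DIFFUSION_METRICS = ("PSMD", "PSFA", "PSAD", "PSRD", "avg_MD", "avg_FA", "avg_AD", "avg_RD")
TOPOLOGY_METRICS = ("Eg", "Eloc", "gamma", "lambda", "sigma", "assortativity",
                    "modularity", "hierarchy")
COVARIATE_COLUMNS = ("age", "sex", "education", "tiv")


@dataclass
class RunConfig:
    """All pipeline parameters with study defaults.

    Defaults follow the source protocol where one is stated: analysis-mask
    FA threshold 0.3, 5th/95th percentiles, tracking angle 45 deg, FA stop
    0.2; the remaining knobs are package design decisions.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    skeleton_fa_min: float = 0.2
    fa_mask_threshold: float = 0.3
    lo_pct: float = 5.0
    hi_pct: float = 95.0
    search_radius_vox: int = 8
    fa_stop: float = 0.2
    angle_max_deg: float = 45.0
    min_length_mm: float | None = None
    n_nulls: int = 100
    rewires_per_edge: int = 10
    n_modularity_restarts: int = 10
    regression_metrics: tuple[str, ...] = ("PSMD", "Eg", "lambda")
    seed: int = 0
    run_tractography: bool = True


@dataclass
class RunReport:
    subject_metrics: pd.DataFrame
    group_table: pd.DataFrame
    demographics_table: pd.DataFrame
    roc_table: pd.DataFrame
    delong_table: pd.DataFrame
    partial_corr_table: pd.DataFrame
    regression_table: pd.DataFrame
    provenance: dict


def validate_config(config: RunConfig) -> list[str]:
    """Diagnostic check; returns one problem string per offending field."""
    problems = []
    if not 0.0 <= config.fa_mask_threshold <= 1.0:
        problems.append("fa_mask_threshold must lie in [0, 1]")
    if not 0.0 <= config.skeleton_fa_min <= 1.0:
        problems.append("skeleton_fa_min must lie in [0, 1]")
    if not 0.0 <= config.lo_pct < config.hi_pct <= 100.0:
        problems.append("lo_pct must be < hi_pct, both in [0, 100]")
    if not 0.0 < config.angle_max_deg <= 90.0:
        problems.append("angle_max_deg must lie in (0, 90]")
    if not 0.0 <= config.fa_stop <= 1.0:
        problems.append("fa_stop must lie in [0, 1]")
    if config.search_radius_vox < 0:
        problems.append("search_radius_vox must be >= 0")
    if config.n_nulls < 1:
        problems.append("n_nulls must be >= 1")
    if config.min_length_mm is not None and config.min_length_mm < 0:
        problems.append("min_length_mm must be >= 0")
    if config.cohort.n_patients + config.cohort.n_controls < 2:
        problems.append("cohort must contain at least 2 subjects")
    return problems


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    payload = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in order; identical config+seed => identical report."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))

    from .synthetic import generate_cohort
    from .tractography import build_connectome, fact_track

    t0 = time.time()
    cohort = generate_cohort(config.cohort, make_volumes=True)
    logger.info("stage=simulate n_subjects=%d elapsed=%.1fs",
                len(cohort.subjects), time.time() - t0)

    # --- skeleton from the cohort mean FA -------------------------------
    t0 = time.time()
    fa_vols = [s.volumes["FA"] for s in cohort.subjects]
    ids = [s.subject_id for s in cohort.subjects]
    template = mean_fa(fa_vols, subject_ids=ids)
    skeleton = build_skeleton(template, config.skeleton_fa_min)
    csf_union = np.zeros(template.shape, dtype=bool)
    for s in cohort.subjects:
        if s.csf_mask is not None:
            csf_union |= s.csf_mask
    exclusion = exclusion_from_csf(csf_union)
    mask = make_analysis_mask(skeleton, config.fa_mask_threshold, exclusion)
    logger.info("stage=skeletonize n_voxels=%d n_masked=%d elapsed=%.1fs",
                len(skeleton), int(mask.keep.sum()), time.time() - t0)

    # --- per-subject metrics --------------------------------------------
    rows = []
    for subj in cohort.subjects:
        t0 = time.time()
        try:
            samples = project_to_skeleton(
                subj.volumes, skeleton, config.search_radius_vox, subj.subject_id
            )
            diff = compute_subject_metrics(
                samples, skeleton, mask, config.lo_pct, config.hi_pct
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage=peakwidth subject={subj.subject_id}: {exc}"
            ) from exc
        row = {"subject_id": subj.subject_id, "group": subj.group, **diff.as_dict()}

        if config.run_tractography:
            try:
                streamlines = fact_track(
                    subj.eigenfield,
                    subj.volumes["FA"],
                    fa_stop=config.fa_stop,
                    angle_max_deg=config.angle_max_deg,
                    min_length_mm=config.min_length_mm,
                    seed_mask=subj.tract_mask,
                )
                conn = build_connectome(streamlines, cohort.parcellation)
            except Exception as exc:
                raise RuntimeError(
                    f"stage=tractography subject={subj.subject_id}: {exc}"
                ) from exc
            try:
                topo = compute_topology(
                    conn.weights,
                    n_nulls=config.n_nulls,
                    rewires_per_edge=config.rewires_per_edge,
                    seed=config.seed,
                    n_restarts=config.n_modularity_restarts,
                )
                row.update(topo.as_dict())
            except Exception as exc:
                logger.warning(
                    "stage=graph-metrics subject=%s degenerate connectome (%s); "
                    "recording NaN", subj.subject_id, exc,
                )
                row.update({m: float("nan") for m in TOPOLOGY_METRICS})
        logger.info("stage=subject-metrics subject=%s elapsed=%.1fs",
                    subj.subject_id, time.time() - t0)
        rows.append(row)

    metrics_df = pd.DataFrame(rows)
    table = cohort.table.set_index("subject_id")
    merged = metrics_df.set_index("subject_id").join(
        table[[c for c in table.columns if c != "group"]]
    ).reset_index()

    report = analyze_cohort(merged, config)
    report.provenance.update(
        {
            "n_skeleton_voxels": int(len(skeleton)),
            "n_masked_voxels": int(mask.keep.sum()),
        }
    )
    return report


def analyze_cohort(merged: pd.DataFrame, config: RunConfig) -> RunReport:
    """The statistical battery on a per-subject metrics + scores table."""
    metric_cols = [m for m in DIFFUSION_METRICS + TOPOLOGY_METRICS
                   if m in merged.columns]
    groups = merged["group"].to_numpy()
    labels01 = (groups == "patient").astype(int)
    patients = merged[merged["group"] == "patient"]

    # demographics (t-tests for continuous, chi-square for sex)
    demo_rows = []
    for cov in ("age", "education", "tiv"):
        if cov in merged.columns:
            res = compare_groups(merged[cov].to_numpy(), groups, variable=cov)
            demo_rows.append(_group_row(res))
    if "sex" in merged.columns:
        tab = np.array(
            [
                [
                    int((patients["sex"] == 1).sum()),
                    int((patients["sex"] == 0).sum()),
                ],
                [
                    int((merged.loc[merged["group"] != "patient", "sex"] == 1).sum()),
                    int((merged.loc[merged["group"] != "patient", "sex"] == 0).sum()),
                ],
            ]
        )
        try:
            chi2, p = chi_square_2x2(tab)
            demo_rows.append(
                {"variable": "sex", "test": "chi_square", "statistic": chi2,
                 "p": p, "patients": f"{tab[0,0]}/{tab[0,1]}",
                 "controls": f"{tab[1,0]}/{tab[1,1]}"}
            )
        except ValueError:
            pass
    demographics = pd.DataFrame(demo_rows)

    # group comparisons of imaging metrics
    group_rows = []
    for m in metric_cols:
        vals = merged[m].to_numpy(dtype=float)
        if np.isnan(vals).all() or np.nanstd(vals) == 0:
            continue
        try:
            res = compare_groups(vals, groups, variable=m)
        except ValueError:
            continue
        group_rows.append(_group_row(res))
    group_table = pd.DataFrame(group_rows)

    # ROC per metric, patients as positive class
    roc_rows = []
    roc_by_metric = {}
    for m in metric_cols:
        vals = merged[m].to_numpy(dtype=float)
        if np.isnan(vals).all() or np.nanstd(vals) == 0:
            continue
        res = roc_auc(vals, labels01, metric=m)
        roc_by_metric[m] = res
        roc_rows.append(dataclasses.asdict(res))
    roc_table = pd.DataFrame(roc_rows)

    delong_rows = []
    if "PSMD" in roc_by_metric:
        for other in ("Eg", "lambda"):
            if other not in roc_by_metric:
                continue
            a = merged["PSMD"].to_numpy(dtype=float)
            b = merged[other].to_numpy(dtype=float)
            ok = ~np.isnan(a) & ~np.isnan(b)
            sa = a if not roc_by_metric["PSMD"].flipped else -a
            sb = b if not roc_by_metric[other].flipped else -b
            try:
                p = delong_compare(sa[ok], sb[ok], labels01[ok])
            except ValueError:
                p = float("nan")
            delong_rows.append({"metric_a": "PSMD", "metric_b": other, "p": p})
    delong_table = pd.DataFrame(delong_rows)

    # partial correlations within patients, FDR per metric across scales
    score_cols = [s for s in SCORE_NAMES if s in merged.columns]
    corr_rows = []
    cov_arr = patients[list(COVARIATE_COLUMNS)].to_numpy(dtype=float) \
        if all(c in patients.columns for c in COVARIATE_COLUMNS) else None
    for m in config.regression_metrics:
        if m not in patients.columns:
            continue
        per_metric = []
        for s in score_cols:
            try:
                res = partial_correlation(
                    patients[m].to_numpy(dtype=float),
                    patients[s].to_numpy(dtype=float),
                    cov_arr,
                    scale=s,
                    metric=m,
                )
                per_metric.append(res)
            except ValueError:
                continue
        if per_metric:
            adj = fdr_bh([r.p for r in per_metric])
            for r, a in zip(per_metric, adj):
                r.p_fdr = float(a)
                corr_rows.append(dataclasses.asdict(r))
    partial_corr = pd.DataFrame(corr_rows)

    # hierarchical regression per clinical scale
    reg_rows = []
    reg_results = []
    for s in score_cols:
        y = patients[s].to_numpy(dtype=float)
        if np.isnan(y).all():
            continue
        block1 = patients[list(COVARIATE_COLUMNS)].astype(float) \
            if cov_arr is not None else pd.DataFrame(index=patients.index)
        block2 = patients[[m for m in config.regression_metrics
                           if m in patients.columns]].astype(float)
        if block2.shape[1] == 0:
            continue
        try:
            res = hierarchical_regression(y, block1, block2, dependent=s)
        except ValueError:
            continue
        reg_results.append(res)
    if reg_results:
        adj = fdr_bh([r.model_p for r in reg_results])
        for r, a in zip(reg_results, adj):
            r.model_p_fdr = float(a)
            row = {"dependent": r.dependent, "r2_adj": r.r2_adj, "F": r.f_stat,
                   "model_p": r.model_p, "model_p_fdr": r.model_p_fdr,
                   "r2_block1": r.r2_block1, "r2_full": r.r2_full}
            for name, b in r.betas.items():
                row[f"beta_{name}"] = b
                row[f"t_{name}"] = r.t_values[name]
                row[f"p_{name}"] = r.p_values[name]
                row[f"vif_{name}"] = r.vif[name]
            reg_rows.append(row)
    regression = pd.DataFrame(reg_rows)

    provenance = {
        "software": "psmdnet",
        "version": _version,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "quantile_convention": "linear interpolation (type 7)",
        "weighted_metric_conventions": "Onnela clustering, 1/w path lengths, "
        "strength assortativity, Louvain modularity",
        "normality_test": "Lilliefors-corrected KS",
        "t_test": "pooled variance",
        "chi_square": "no continuity correction",
        "fdr_family": "clinical scales within each metric",
        "analysis_mask": f"mean FA >= {config.fa_mask_threshold} minus dilated CSF",
    }
    return RunReport(
        subject_metrics=merged,
        group_table=group_table,
        demographics_table=demographics,
        roc_table=roc_table,
        delong_table=delong_table,
        partial_corr_table=partial_corr,
        regression_table=regression,
        provenance=provenance,
    )


def _group_row(res: GroupTestResult) -> dict:
    return {
        "variable": res.variable,
        "test": res.test,
        "statistic": res.statistic,
        "p": res.p,
        "patients": res.summary_a,
        "controls": res.summary_b,
    }


def write_report(report: RunReport, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "subject_metrics.tsv": report.subject_metrics,
        "group_comparison.tsv": report.group_table,
        "demographics.tsv": report.demographics_table,
        "roc.tsv": report.roc_table,
        "delong.tsv": report.delong_table,
        "partial_correlation.tsv": report.partial_corr_table,
        "regression.tsv": report.regression_table,
    }
    for name, df in tables.items():
        df.to_csv(out / name, sep="\t", index=False)
    with open(out / "provenance.json", "w") as fh:
        json.dump(report.provenance, fh, indent=2, sort_keys=True)


def config_from_yaml(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file of (nested) overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_kwargs = raw.pop("cohort", {})
    phantom_kwargs = cohort_kwargs.pop("phantom", {}) if cohort_kwargs else {}
    from .synthetic import PhantomConfig

    cohort = CohortConfig(
        **cohort_kwargs, **({"phantom": PhantomConfig(**phantom_kwargs)}
                            if phantom_kwargs else {})
    )
    return RunConfig(cohort=cohort, **raw)
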
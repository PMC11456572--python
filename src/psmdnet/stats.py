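"""Group statistics: normality-gated two-sample tests, chi-square, ROC with
DeLong comparisons, covariate-adjusted partial correlation, hierarchical
regression with VIF, and Benjamini-Hochberg FDR.

Conventions: normality is assessed per group with the Lilliefors-corrected
Kolmogorov-Smirnov test (parameters estimated from the data); the two-sample
t-test uses pooled variance; the Mann-Whitney U test reports a tie-corrected
normal-approximation Z; chi-square omits the continuity correction; ROC
curves are oriented so AUC >= 0.5 (flip recorded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.linear_model import OLS
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests
from statsmodels.tools import add_constant


# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------


@dataclass
class GroupTestResult:
    variable: str
    test: str  # pooled_t | mann_whitney | chi_square
    statistic: float
    p: float
    summary_a: str
    summary_b: str
    normal_a: bool | None = None
    normal_b: bool | None = None
    n_a: int = 0
    n_b: int = 0


@dataclass
class RocResult:
    metric: str
    auc: float
    ci_low: float
    ci_high: float
    p: float
    flipped: bool
    n_pos: int
    n_neg: int


@dataclass
class PartialCorrResult:
    scale: str
    metric: str
    r: float
    p: float
    p_fdr: float = float("nan")
    n: int = 0


@dataclass
class RegressionResult:
    dependent: str
    betas: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    vif: dict[str, float]
    r2_adj: float
    f_stat: float
    model_p: float
    model_p_fdr: float = float("nan")
    r2_full: float = float("nan")
    r2_block1: float = float("nan")


# ---------------------------------------------------------------------------
# two-group comparison
# ---------------------------------------------------------------------------


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if len(x) < 4 or np.ptp(x) == 0:
        # Lilliefors needs n >= 4; tiny/constant groups treated as normal
        return True
    _, p = lilliefors(x, dist="norm")
    return bool(p >= alpha)


def _summary(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{np.mean(x):.4g} ± {np.std(x, ddof=1):.4g}"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.4g} ({q1:.4g}, {q3:.4g})"


def mann_whitney_z(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """U statistic (of the first sample), tie-corrected Z and two-sided p."""
    n1, n2 = len(a), len(b)
    ranks = sps.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    if var <= 0:
        return u1, 0.0, 1.0
    z = (u1 - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return u1, float(z), float(min(p, 1.0))


def compare_groups(
    values: np.ndarray,
    groups: np.ndarray,
    variable: str = "value",
    alpha_normality: float = 0.05,
) -> GroupTestResult:
    """KS(Lilliefors)-gated pooled t-test or Mann-Whitney U between two groups.

    ``groups`` holds exactly two labels; the first label encountered is
    group A.  NaN values are dropped pairwise.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(labels)}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    for name, g in ((labels[0], a), (labels[1], b)):
        if len(g) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 subjects")
    norm_a = _is_normal(a, alpha_normality)
    norm_b = _is_normal(b, alpha_normality)
    if norm_a and norm_b:
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=True)
        test = "pooled_t"
    else:
        _, stat, p = mann_whitney_z(a, b)
        test = "mann_whitney"
    return GroupTestResult(
        variable=variable,
        test=test,
        statistic=float(stat),
        p=float(p),
        summary_a=_summary(a, norm_a),
        summary_b=_summary(b, norm_b),
        normal_a=norm_a,
        normal_b=norm_b,
        n_a=len(a),
        n_b=len(b),
    )


def chi_square_2x2(counts: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on a 2x2 table."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (2, 2) or np.any(c < 0) or np.any(c != np.round(c)):
        raise ValueError("counts must be a 2x2 table of non-negative integers")
    n = c.sum()
    r = c.sum(axis=1)
    col = c.sum(axis=0)
    if np.any(r == 0) or np.any(col == 0):
        raise ValueError("zero margin in contingency table")
    num = (c[0, 0] * c[1, 1] - c[0, 1] * c[1, 0]) ** 2 * n
    chi2 = num / (r[0] * r[1] * col[0] * col[1])
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01, float(psi.mean())


def roc_auc(scores: np.ndarray, labels: np.ndarray, metric: str = "score") -> RocResult:
    """AUC (rank statistic with half-credit ties) and DeLong 95% CI / p.

    Positive class is ``labels == 1`` (patients).  If the raw AUC is below
    0.5 the scores are inverted and the flip flagged.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    ok = ~np.isnan(scores)
    scores, labels = scores[ok], labels[ok]
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    flipped = False
    v10, v01, auc = _placements(pos, neg)
    if auc < 0.5:
        flipped = True
        v10, v01, auc = _placements(-pos, -neg)
    var = 0.0
    if len(pos) > 1:
        var += np.var(v10, ddof=1) / len(pos)
    if len(neg) > 1:
        var += np.var(v01, ddof=1) / len(neg)
    se = np.sqrt(var)
    if se > 0:
        ci_low = max(0.0, auc - 1.959963984540054 * se)
        ci_high = min(1.0, auc + 1.959963984540054 * se)
        p = 2.0 * sps.norm.sf(abs(auc - 0.5) / se)
    else:
        ci_low = ci_high = auc
        p = 1.0 if auc == 0.5 else 0.0
    return RocResult(metric, float(auc), float(ci_low), float(ci_high),
                     float(min(p, 1.0)), flipped, len(pos), len(neg))


def delong_compare(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> float:
    """Two-sided paired DeLong test comparing two AUCs on the same subjects."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    if np.array_equal(scores_a, scores_b):
        raise ValueError("degenerate comparison (identical score vectors)")
    pos_mask, neg_mask = labels == 1, labels == 0
    if not pos_mask.any() or not neg_mask.any():
        raise ValueError("both classes must be present")
    v10a, v01a, auc_a = _placements(scores_a[pos_mask], scores_a[neg_mask])
    v10b, v01b, auc_b = _placements(scores_b[pos_mask], scores_b[neg_mask])
    m, n = int(pos_mask.sum()), int(neg_mask.sum())
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = 0.0
    if m > 1:
        var += np.var(d10, ddof=1) / m
    if n > 1:
        var += np.var(d01, ddof=1) / n
    diff = auc_a - auc_b
    if var <= 1e-24:
        if abs(diff) < 1e-12:
            return 1.0  # identical placements (e.g. monotone transform)
        raise ValueError("degenerate comparison (zero variance of AUC difference)")
    z = diff / np.sqrt(var)
    return float(min(2.0 * sps.norm.sf(abs(z)), 1.0))


# ---------------------------------------------------------------------------
# partial correlation / regression
# ---------------------------------------------------------------------------


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    scale: str = "y",
    metric: str = "x",
) -> PartialCorrResult:
    """Correlation of x and y after residualizing both on the covariates.

    p from a t distribution with df = n - 2 - k.  With no covariates this is
    the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        Z = np.empty((len(x), 0))
    else:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != len(x):
            Z = Z.T
    ok = ~np.isnan(x) & ~np.isnan(y) & ~np.isnan(Z).any(axis=1)
    x, y, Z = x[ok], y[ok], Z[ok]
    n, k = len(x), Z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariates collinear with the intercept")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    if rx.std() < 1e-14 * max(1.0, np.abs(x).max()) or ry.std() < 1e-14 * max(
        1.0, np.abs(y).max()
    ):
        raise ValueError("residual variance is zero (variable collinear with covariates)")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_clip = min(max(r, -0.999999999999), 0.999999999999)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return PartialCorrResult(scale=scale, metric=metric, r=r, p=p, n=n)


def _zscore(a: np.ndarray) -> np.ndarray:
    return (a - a.mean(axis=0)) / a.std(axis=0, ddof=1)


def _name_collinear(X: pd.DataFrame) -> str | None:
    arr = add_constant(X.to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(arr) == arr.shape[1]:
        return None
    for j, name in enumerate(X.columns):
        others = np.delete(arr, j + 1, axis=1)
        beta, res, *_ = np.linalg.lstsq(others, arr[:, j + 1], rcond=None)
        resid = arr[:, j + 1] - others @ beta
        if np.abs(resid).max() < 1e-8 * max(1.0, np.abs(arr[:, j + 1]).max()):
            return str(name)
    return str(X.columns[-1])


def hierarchical_regression(
    y: np.ndarray,
    block1: pd.DataFrame,
    block2: pd.DataFrame,
    dependent: str = "y",
) -> RegressionResult:
    """Covariates-first hierarchical linear model.

    Fits block1 alone, then block1 + block2; reports standardized betas, t
    and p for the block-2 predictors from the full model, the full-model
    adjusted R^2 / F / p, the block-1 and full R^2, and per-predictor VIFs.
    """
    y = np.asarray(y, dtype=float)
    X = pd.concat([block1, block2], axis=1)
    ok = ~np.isnan(y) & ~X.isna().any(axis=1).to_numpy()
    y, X = y[ok], X.loc[ok]
    b1 = block1.loc[ok]
    n, p_tot = X.shape
    if n <= p_tot + 1:
        raise ValueError(f"need n > predictors + 1 (n={n}, predictors={p_tot})")
    bad = _name_collinear(X)
    if bad is not None:
        raise ValueError(f"singular design: column {bad!r} is collinear")

    full = OLS(y, add_constant(X.to_numpy(dtype=float))).fit()
    base = OLS(y, add_constant(b1.to_numpy(dtype=float))).fit() if b1.shape[1] else None

    # standardized betas: z-score y and predictors, refit
    Xz = _zscore(X.to_numpy(dtype=float))
    yz = _zscore(y)
    std_fit = OLS(yz, add_constant(Xz)).fit()

    names = list(X.columns)
    betas, tvals, pvals, vifs = {}, {}, {}, {}
    arr = X.to_numpy(dtype=float)
    for j, name in enumerate(names):
        if name in block2.columns:
            betas[name] = float(std_fit.params[j + 1])
            tvals[name] = float(full.tvalues[j + 1])
            pvals[name] = float(full.pvalues[j + 1])
        others = np.delete(arr, j, axis=1)
        r2_j = OLS(arr[:, j], add_constant(others)).fit().rsquared
        vifs[name] = float(1.0 / max(1.0 - r2_j, 1e-12))

    return RegressionResult(
        dependent=dependent,
        betas=betas,
        t_values=tvals,
        p_values=pvals,
        vif=vifs,
        r2_adj=float(full.rsquared_adj),
        f_stat=float(full.fvalue),
        model_p=float(full.f_pvalue),
        r2_full=float(full.rsquared),
        r2_block1=float(base.rsquared) if base is not None else 0.0,
    )


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def fdr_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj
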
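"""Covariate-adjusted group comparisons, FDR correction, and correlations.

Covariates (age, sex coded male=1/female=0, mean frame-wise displacement)
are handled by residualization: metric AUCs are regressed on
intercept + covariates across the pooled sample and the group test runs on
the residuals, which matches the ANCOVA group term up to degree-of-freedom
bookkeeping. The three pairwise contrasts (HC vs pre, HC vs post, pre vs
post) are corrected together by Benjamini-Hochberg FDR over the whole
metric x contrast family of one analysis run. All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (CollinearityError, DegenerateVarianceError,
                     InsufficientDataError)

CONTRASTS = ("HC_vs_pre", "HC_vs_post", "pre_vs_post")


@dataclass
class ComparisonResult:
    metric_name: str
    contrast: str
    statistic: float
    p_raw: float
    df: float
    direction: int  # sign of (first group mean - second group mean)
    p_fdr: float = np.nan


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    r: float
    p: float
    n: int


def residualize(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Least-squares residuals of ``values`` on intercept + covariates.

    ``covariates`` is an (n_subjects, k) design without the intercept
    column; a rank-deficient design raises, naming the offending column.
    """
    y = np.asarray(values, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if len(y) != cov.shape[0]:
        raise ValueError("one value per subject required")
    design = np.column_stack([np.ones(len(y)), cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        for j in range(1, design.shape[1]):
            reduced = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise CollinearityError(
                    f"covariate column {j - 1} is collinear with the rest "
                    "of the design")
        raise CollinearityError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def two_sample_test(a: np.ndarray, b: np.ndarray,
                    metric_name: str = "", contrast: str = "") -> ComparisonResult:
    """Student two-sample t (pooled variance), two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need at least 2 observations per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            # identical constant groups: no evidence of difference
            return ComparisonResult(metric_name, contrast, 0.0, 1.0,
                                    len(a) + len(b) - 2, 0)
        raise DegenerateVarianceError("zero pooled variance")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    df = len(a) + len(b) - 2
    direction = int(np.sign(np.mean(a) - np.mean(b)))
    return ComparisonResult(metric_name, contrast, float(t), float(p),
                            df, direction)


def paired_test(pre: np.ndarray, post: np.ndarray,
                metric_name: str = "",
                contrast: str = "pre_vs_post") -> ComparisonResult:
    """Paired t on within-subject differences (post - pre), two-sided."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if len(pre) != len(post):
        raise ValueError("paired inputs must have equal length")
    if len(pre) < 2:
        raise InsufficientDataError("need at least 2 pairs")
    d = post - pre
    if np.var(d, ddof=1) == 0:
        raise DegenerateVarianceError(
            "zero variance of paired differences")
    t, p = stats.ttest_rel(post, pre)
    direction = int(np.sign(np.mean(d)))
    return ComparisonResult(metric_name, contrast, float(t), float(p),
                            len(pre) - 1, direction)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def correlate_with_symptoms(x_change, y_change, x_name: str = "x",
                            y_name: str = "y") -> CorrelationResult:
    """Pearson r between paired per-patient changes, two-sided p via the
    t transform."""
    x = np.asarray(x_change, dtype=float)
    y = np.asarray(y_change, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must be paired")
    if len(x) < 3:
        raise InsufficientDataError("correlation needs n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise DegenerateVarianceError("zero variance input to correlation")
    res = stats.pearsonr(x, y)
    return CorrelationResult(x_name, y_name, float(res.statistic),
                             float(res.pvalue), len(x))


def compare_auc_tables(
    auc_by_group: dict[str, dict[str, np.ndarray]],
    covariates_by_group: dict[str, np.ndarray] | None = None,
    paired_key: tuple[str, str] = ("pre", "post"),
) -> list[ComparisonResult]:
    """All metric x contrast comparisons with one family-wide BH correction.

    ``auc_by_group`` maps group key ("HC", "pre", "post") to a dict of
    metric name -> per-subject AUC vector. When covariates are supplied the
    unpaired contrasts run on pooled residuals; the paired contrast uses the
    raw within-subject differences (covariates are constant within subject).
    """
    results: list[ComparisonResult] = []
    metrics = list(next(iter(auc_by_group.values())).keys())
    for metric in metrics:
        for ga, gb, contrast in (("HC", "pre", "HC_vs_pre"),
                                 ("HC", "post", "HC_vs_post")):
            if ga not in auc_by_group or gb not in auc_by_group:
                continue
            a = np.asarray(auc_by_group[ga][metric], dtype=float)
            b = np.asarray(auc_by_group[gb][metric], dtype=float)
            if covariates_by_group is not None:
                pooled = np.concatenate([a, b])
                cov = np.vstack([covariates_by_group[ga],
                                 covariates_by_group[gb]])
                resid = residualize(pooled, cov)
                a, b = resid[:len(a)], resid[len(a):]
            results.append(two_sample_test(a, b, metric, contrast))
        ka, kb = paired_key
        if ka in auc_by_group and kb in auc_by_group:
            results.append(paired_test(
                np.asarray(auc_by_group[ka][metric], dtype=float),
                np.asarray(auc_by_group[kb][metric], dtype=float),
                metric))
    p_adj = fdr_bh([r.p_raw for r in results])
    for r, q in zip(results, p_adj):
        r.p_fdr = float(q)
    return results
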
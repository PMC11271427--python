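"""Cohort-level statistics: percent changes and restoration ratios,
afferent-function Pearson correlations with confidence intervals, PCA
composite functionality scores, and normality-gated group comparisons
with Holm-Šidák correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "CompositeScore",
    "GroupComparison",
    "percent_increase",
    "absolute_increase",
    "restoration_ratio",
    "round_half_away",
    "pearson_with_ci",
    "pca_composite",
    "group_compare",
    "group_compare_family",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (so 186.5 ->
    187 and -4.5 -> -5), matching how percentages are reported."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def percent_increase(a: float, b: float) -> dict:
    """Percent increase of ``a`` over the reference ``b``:
    100*(a - b)/b, reported raw and integer-rounded."""
    if b == 0:
        raise ZeroDivisionError("percent increase undefined for zero reference")
    raw = 100.0 * (a - b) / b
    return {"raw": raw, "rounded": round_half_away(raw)}


def absolute_increase(a: float, b: float) -> float:
    """Absolute increase a - b, for metrics reported as differences in
    physical units (e.g. net work in J/kg)."""
    return a - b


def restoration_ratio(value: float, intact_ref: float) -> dict:
    """Fraction of the biologically intact reference restored:
    100*value/intact_ref, raw and integer-rounded."""
    if intact_ref <= 0:
        raise ValueError(f"intact reference must be positive, got {intact_ref}")
    raw = 100.0 * value / intact_ref
    return {"raw": raw, "rounded": round_half_away(raw)}


@dataclass
class CorrelationResult:
    """Pearson r with Fisher-z 95% CI, OLS slope with its 95% CI, and the
    two-sided p value."""

    r: float
    ci_95: tuple[float, float]
    slope: float
    slope_ci_95: tuple[float, float]
    intercept: float
    p: float
    n: int


def pearson_with_ci(x, y) -> CorrelationResult:
    """Sample Pearson correlation with Fisher-z 95% CI for r, plus the
    ordinary least-squares slope and its t-based 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need at least 3 paired finite observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    r, p = stats.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se_z = 1.0 / math.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.975)
    ci = (float(np.tanh(z - zcrit * se_z)), float(np.tanh(z + zcrit * se_z)))
    fit = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, n - 2)
    slope_ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    return CorrelationResult(float(r), ci, float(fit.slope),
                             (float(slope_ci[0]), float(slope_ci[1])),
                             float(fit.intercept), float(p), int(n))


@dataclass
class CompositeScore:
    """First principal component of the z-scored metric matrix."""

    pc1_loadings: pd.Series
    pc1_scores: pd.Series
    variance_explained: float
    sign_column: str


def pca_composite(metrics: pd.DataFrame, flip_columns: tuple[str, ...] = (),
                  sign_column: str | None = None) -> CompositeScore:
    """PC1 composite functionality score.

    Columns are z-scored (so the PCA acts on the correlation matrix),
    ``flip_columns`` are negated first (stair-descent peak power and net
    work carry a biomimetic-negative sign), and PC1 is oriented so the
    loading on ``sign_column`` (default: the first column) is positive —
    higher scores mean more biomimetic function.  Missing cells are
    refused, constant columns named in the error.
    """
    if metrics.isna().any().any():
        bad = metrics.columns[metrics.isna().any()].tolist()
        raise ValueError(f"missing cells in columns {bad}; imputation refused")
    if metrics.shape[1] < 2:
        raise ValueError("PCA needs at least 2 metric columns")
    X = metrics.astype(float).copy()
    for c in flip_columns:
        if c not in X.columns:
            raise ValueError(f"flip column {c!r} not in metrics")
        X[c] = -X[c]
    sd = X.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant column(s) {constant}: PCA undefined")
    Z = (X - X.mean()) / sd
    corr = np.cov(Z.to_numpy(), rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(corr)
    pc1 = evecs[:, -1]
    var_exp = float(evals[-1] / evals.sum())
    sign_column = sign_column or str(metrics.columns[0])
    j = list(metrics.columns).index(sign_column)
    if pc1[j] < 0:
        pc1 = -pc1
    loadings = pd.Series(pc1, index=metrics.columns)
    scores = pd.Series(Z.to_numpy() @ pc1, index=metrics.index)
    return CompositeScore(loadings, scores, var_exp, sign_column)


@dataclass
class GroupComparison:
    """Result of one normality-gated two-group comparison."""

    test: str                # "t_paired" | "t_unpaired" | "mannwhitney"
    statistic: float
    p: float
    p_adjusted: float | None = None
    shapiro_p: dict = field(default_factory=dict)
    normal: bool = True


def _single_compare(x: np.ndarray, y: np.ndarray, paired: bool,
                    alpha: float = 0.05) -> GroupComparison:
    sw_x = stats.shapiro(x).pvalue
    sw_y = stats.shapiro(y).pvalue
    normal = (sw_x > alpha) and (sw_y > alpha)
    if normal:
        if paired:
            res = stats.ttest_rel(x, y)
            name = "t_paired"
        else:
            res = stats.ttest_ind(x, y)
            name = "t_unpaired"
        stat, p = res.statistic, res.pvalue
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        name, stat, p = "mannwhitney", res.statistic, res.pvalue
    return GroupComparison(name, float(stat), float(p),
                           shapiro_p={"x": float(sw_x), "y": float(sw_y)},
                           normal=normal)


def group_compare(x, y, paired: bool = False,
                  alpha: float = 0.05) -> GroupComparison:
    """One normality-gated two-group comparison.

    Shapiro-Wilk (alpha = 0.05) on both groups gates a two-sided t-test
    (paired or unpaired) versus a Mann-Whitney U-test; the report records
    which branch fired.  The adjusted p equals the raw p (a family of
    one); use :func:`group_compare_family` for multiple comparisons.
    """
    return group_compare_family([(x, y)], paired=paired, alpha=alpha)[0]


def group_compare_family(pairs, paired: bool = False,
                         alpha: float = 0.05) -> list[GroupComparison]:
    """A declared Holm-Šidák comparison family of ``(x, y)`` pairs.

    Each pair runs through the same normality gate as
    :func:`group_compare`; adjusted p values follow the Holm-Šidák
    step-down procedure across the family (identity for one comparison).
    """
    results = []
    for x, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if min(x.size, y.size) < 3:
            raise ValueError("group sizes must be >= 3")
        if paired and x.size != y.size:
            raise ValueError(
                f"paired comparison with unequal lengths ({x.size} vs {y.size})")
        results.append(_single_compare(x, y, paired, alpha))
    pvals = [r.p for r in results]
    _, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="holm-sidak")
    for r, pa in zip(results, p_adj):
        r.p_adjusted = float(pa)
    return results
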
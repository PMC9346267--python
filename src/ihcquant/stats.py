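"""Agreement and discrimination statistics for method validation.

Implements the validation layer used to compare measurement methods and
observers: Lin's concordance correlation coefficient (CCC) with its
asymptotic confidence interval and agreement categories, Spearman rank
correlation, Kruskal-Wallis / one-way ANOVA location tests, and ROC
analysis with a Youden-index cut-off, DeLong confidence intervals and the
DeLong paired test for correlated AUCs.

The CCC measures agreement, not mere association: it penalizes location
and scale shifts, equals 1 only when the two vectors are identical, and
never exceeds the Pearson correlation in magnitude.  Agreement categories
follow the conventional thresholds: below 0.800 no agreement, 0.800-0.950
acceptable, 0.950 and above strong.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CCCResult",
    "ROCResult",
    "concordance_correlation",
    "spearman_correlation",
    "group_location_test",
    "roc_analysis",
    "compare_auc",
]

CCC_ACCEPTABLE = 0.800
CCC_STRONG = 0.950


@dataclass(frozen=True)
class CCCResult:
    ccc: float
    ci_low: float
    ci_high: float
    category: str  # "none" | "acceptable" | "strong"
    n: int


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    best_cutoff: float
    sensitivity: float  # percent, at best_cutoff
    specificity: float  # percent, at best_cutoff
    direction: str  # "higher": larger score predicts the positive class
    n_positive: int
    n_negative: int


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _ccc_category(ccc: float) -> str:
    if ccc >= CCC_STRONG:
        return "strong"
    if ccc >= CCC_ACCEPTABLE:
        return "acceptable"
    return "none"


def concordance_correlation(
    x, y, *, bias_corrected: bool = False, alpha: float = 0.05
) -> CCCResult:
    """Lin's concordance correlation coefficient with 95% CI.

    CCC = 2*cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2), using
    population (1/n) moments by default; ``bias_corrected`` switches to
    1/(n-1) moments.  The confidence interval applies a Fisher
    z-transformation with Lin's asymptotic standard error.
    """
    x = _as_vector(x, "x")
    y = _as_vector(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")

    ddof = 1 if bias_corrected else 0
    mx, my = x.mean(), y.mean()
    sx2 = x.var(ddof=ddof)
    sy2 = y.var(ddof=ddof)
    sxy = ((x - mx) * (y - my)).sum() / (n - ddof)
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("both vectors are constant and equal; CCC undefined")
    ccc = 2.0 * sxy / denom

    z_crit = sps.norm.ppf(1.0 - alpha / 2.0)
    if sx2 > 0 and sy2 > 0:
        r = sxy / math.sqrt(sx2 * sy2)
    else:
        r = 0.0
    if abs(ccc) >= 1.0 - 1e-12:
        lo = hi = ccc
    else:
        u2 = (mx - my) ** 2 / math.sqrt(sx2 * sy2) if sx2 > 0 and sy2 > 0 else 0.0
        se2 = math.nan
        if abs(r) > 1e-12:
            se2 = (
                (1 - r**2) * ccc**2 / ((1 - ccc**2) * r**2)
                + 2 * ccc**3 * (1 - ccc) * u2 / (r * (1 - ccc**2) ** 2)
                - ccc**4 * u2**2 / (2 * r**2 * (1 - ccc**2) ** 2)
            ) / (n - 2)
        if not (math.isfinite(se2) and se2 >= 0):
            # degenerate geometry (r ~ 0); fall back to the plain Fisher SE
            se2 = 1.0 / max(n - 3, 1)
        z = math.atanh(ccc)
        half = z_crit * math.sqrt(se2)
        lo, hi = math.tanh(z - half), math.tanh(z + half)
    return CCCResult(
        ccc=float(ccc),
        ci_low=float(min(lo, ccc)),
        ci_high=float(max(hi, ccc)),
        category=_ccc_category(ccc),
        n=n,
    )


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) and two-sided p."""
    x = _as_vector(x, "x")
    y = _as_vector(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def group_location_test(groups, method: str = "kruskal") -> tuple[float, float]:
    """Compare locations of two or more independent groups.

    ``method='kruskal'``: Kruskal-Wallis H with tie correction and a
    chi-square p-value.  ``method='anova'``: one-way ANOVA F test.
    """
    groups = [_as_vector(g, "group") for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    if method == "kruskal":
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:
            return 0.0, 1.0  # all observations identical: no evidence of shift
        stat, p = sps.kruskal(*groups)
    elif method == "anova":
        stat, p = sps.f_oneway(*groups)
        if math.isnan(p):  # zero within-group variance everywhere, equal means
            return 0.0, 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(stat), float(p)


# --- ROC / DeLong ---------------------------------------------------------


def _check_binary(labels) -> np.ndarray:
    lab = np.asarray(labels).ravel()
    classes = np.unique(lab)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    return lab == classes.max()


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """AUC and DeLong structural components via mid-ranks."""
    m, n = pos.size, neg.size
    combined = np.concatenate([pos, neg])
    rz = sps.rankdata(combined)
    rp = sps.rankdata(pos)
    rn = sps.rankdata(neg)
    auc = (rz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rz[:m] - rp) / n
    v01 = 1.0 - (rz[m:] - rn) / m
    return auc, v10, v01


def _auc_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    s10 = v10.var(ddof=1) / v10.size if v10.size > 1 else 0.0
    s01 = v01.var(ddof=1) / v01.size if v01.size > 1 else 0.0
    return s10 + s01


def roc_analysis(
    scores,
    labels,
    *,
    auto_direction: bool = True,
    alpha: float = 0.05,
) -> ROCResult:
    """Empirical ROC with DeLong CI and the Youden-index cut-off.

    The AUC is the Mann-Whitney concordance probability (trapezoidal rule
    over the empirical curve).  The reported cut-off is the midpoint
    between consecutive distinct observed scores maximizing Youden's
    J = sensitivity + specificity - 1; ties in J resolve to the lower
    cut-off.  When the raw AUC is below 0.5 and ``auto_direction`` is on,
    the decision direction flips ("lower" score predicts the positive
    class) so a negatively associated predictor still reports AUC > 0.5.
    """
    scores = _as_vector(scores, "scores")
    is_pos = _check_binary(labels)
    if scores.size != is_pos.size:
        raise ValueError("scores and labels must have equal length")

    eff = scores.copy()
    direction = "higher"
    auc, _, _ = _delong_components(eff[is_pos], eff[~is_pos])
    if auto_direction and auc < 0.5:
        eff = -eff
        direction = "lower"
    auc, v10, v01 = _delong_components(eff[is_pos], eff[~is_pos])
    se = math.sqrt(_auc_variance(v10, v01))
    z_crit = sps.norm.ppf(1.0 - alpha / 2.0)
    ci_low = max(0.0, auc - z_crit * se)
    ci_high = min(1.0, auc + z_crit * se)

    distinct = np.unique(eff)
    if distinct.size > 1:
        cutoffs = (distinct[:-1] + distinct[1:]) / 2.0
    else:
        cutoffs = distinct
    n_pos = int(is_pos.sum())
    n_neg = int(is_pos.size - n_pos)
    best = (-np.inf, math.nan, math.nan, math.nan)
    for c in cutoffs:  # ascending: strict > keeps the lowest argmax
        sens = np.count_nonzero(eff[is_pos] > c) / n_pos
        spec = np.count_nonzero(eff[~is_pos] <= c) / n_neg
        j = sens + spec - 1.0
        if j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    _, cut_eff, sens, spec = best
    best_cutoff = -cut_eff if direction == "lower" else cut_eff

    return ROCResult(
        auc=float(auc),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        best_cutoff=float(best_cutoff),
        sensitivity=float(100.0 * sens),
        specificity=float(100.0 * spec),
        direction=direction,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def compare_auc(scores_a, scores_b, labels) -> float:
    """DeLong paired test for two correlated ROC curves; two-sided p.

    Both score vectors must be measured on the same subjects with the
    same outcome labels.  Identical curves (including any strictly
    monotone transform of one another) give p = 1.
    """
    a = _as_vector(scores_a, "scores_a")
    b = _as_vector(scores_b, "scores_b")
    is_pos = _check_binary(labels)
    if not (a.size == b.size == is_pos.size):
        raise ValueError("paired scores and labels must have equal length")

    auc_a, v10a, v01a = _delong_components(a[is_pos], a[~is_pos])
    auc_b, v10b, v01b = _delong_components(b[is_pos], b[~is_pos])
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = _auc_variance(d10, d01)
    diff = auc_a - auc_b
    if var <= 1e-16:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / math.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))
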
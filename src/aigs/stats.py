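"""Evaluation statistics for screening models.

Covers segmentation overlap (Dice), ROC analysis with percentile-bootstrap
confidence intervals and the Youden operating point, DeLong's test for
correlated AUCs, Bland-Altman agreement, threshold sweeps, correlation
comparison between groups with bootstrap difference tests, and histogram
summaries (peak, FWHM, cumulative probability).

Conventions: a decision is positive when score >= threshold; bootstrap
intervals are plain percentile intervals (B = 2000 by default, 95% level);
differences in :func:`bland_altman` are ``a - b``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

__all__ = [
    "RocResult", "AgreementResult", "CorrelationComparison",
    "HistogramSummary", "dice_coefficient", "roc_analysis",
    "youden_threshold", "delong_test", "bland_altman", "threshold_sweep",
    "correlation_compare", "histogram_summary", "auc_mann_whitney",
]


# ---------------------------------------------------------------------------
# Dice

def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|) on boolean masks; 1.0 when both are empty."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("masks must share one shape")
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (pred & truth).sum() / denom)


# ---------------------------------------------------------------------------
# ROC / AUC

def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUC; identical to the trapezoidal ROC area."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = labels.sum(), (~labels).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    ranks = sps.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def youden_threshold(scores: np.ndarray,
                     labels: np.ndarray) -> tuple[float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties are broken toward the larger threshold. The returned threshold is
    an observed score (decision rule: score >= threshold is positive).
    """
    fpr, tpr, thr = roc_curve(labels, scores)
    j = tpr - fpr
    best = int(np.argmax(j))          # thresholds descend: first = largest
    t = thr[best]
    if np.isinf(t):                   # degenerate: everything negative
        t = thr[1] if len(thr) > 1 else np.max(scores)
    return float(t), float(j[best])


def _threshold_metrics(scores, labels, threshold):
    pred = scores >= threshold
    labels = labels.astype(bool)
    tp = (pred & labels).sum()
    tn = (~pred & ~labels).sum()
    sens = tp / labels.sum() if labels.any() else np.nan
    spec = tn / (~labels).sum() if (~labels).any() else np.nan
    acc = (pred == labels).mean()
    return float(sens), float(spec), float(acc)


@dataclasses.dataclass
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    youden_threshold: float
    youden_j: float
    sensitivity: float
    specificity: float
    accuracy: float
    ci: dict[str, tuple[float, float]]


def roc_analysis(scores: np.ndarray, labels: np.ndarray,
                 n_boot: int = 2000, seed: int = 0,
                 level: float = 0.95) -> RocResult:
    """ROC curve, trapezoidal AUC, Youden point, and percentile-bootstrap
    CIs for AUC/sensitivity/specificity/accuracy at that point."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = auc_mann_whitney(scores, labels)
    t_star, j = youden_threshold(scores, labels)
    sens, spec, acc = _threshold_metrics(scores, labels, t_star)
    rng = np.random.default_rng(seed)
    n = len(scores)
    boots = {"auc": [], "sensitivity": [], "specificity": [], "accuracy": []}
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        lb = labels[idx]
        if lb.min() == lb.max():
            continue
        sc = scores[idx]
        boots["auc"].append(auc_mann_whitney(sc, lb))
        s_, p_, a_ = _threshold_metrics(sc, lb, t_star)
        boots["sensitivity"].append(s_)
        boots["specificity"].append(p_)
        boots["accuracy"].append(a_)
    lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    ci = {k: (float(np.percentile(v, lo)), float(np.percentile(v, hi)))
          if v else (np.nan, np.nan) for k, v in boots.items()}
    return RocResult(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc,
                     youden_threshold=t_star, youden_j=j,
                     sensitivity=sens, specificity=spec, accuracy=acc, ci=ci)


def threshold_sweep(scores: np.ndarray, labels: np.ndarray,
                    grid: np.ndarray) -> pd.DataFrame:
    """Sensitivity/specificity/accuracy as functions of the threshold."""
    rows = []
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    for t in np.asarray(grid, dtype=float):
        sens, spec, acc = _threshold_metrics(scores, labels, t)
        rows.append({"threshold": t, "sensitivity": sens,
                     "specificity": spec, "accuracy": acc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DeLong's test

def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> tuple[float, float, float]:
    """DeLong's z-test for the difference of two correlated AUCs.

    Both score vectors must be paired on the same cases/labels. Returns
    (AUC_A, AUC_B, two-sided p). When the variance of the AUC difference
    is zero (e.g. identical scores), p = 1 by convention.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("scores and labels must be paired")
    if labels.all() or not labels.any():
        raise ValueError("labels must contain both classes")
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var <= 1e-16:
        return float(auc_a), float(auc_b), 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(p)


# ---------------------------------------------------------------------------
# Bland-Altman

@dataclasses.dataclass
class AgreementResult:
    bias: float
    sd: float
    limits: tuple[float, float]      # bias -/+ 1.96 sd
    percent_within: float


def bland_altman(a: np.ndarray, b: np.ndarray) -> AgreementResult:
    """Agreement between paired measurements; differences are ``a - b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("inputs must be paired")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    within = float(100.0 * ((d >= lo) & (d <= hi)).mean())
    return AgreementResult(bias=bias, sd=sd, limits=(float(lo), float(hi)),
                           percent_within=within)


# ---------------------------------------------------------------------------
# correlation comparison

@dataclasses.dataclass
class CorrelationComparison:
    corr_a: pd.DataFrame
    corr_b: pd.DataFrame
    method: pd.DataFrame             # 'pearson' | 'spearman' per pair
    difference: pd.DataFrame         # corr_a - corr_b
    p_values: pd.DataFrame
    stars: pd.DataFrame


def _star(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return "*" if p < 0.05 else ""


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    return float(sps.spearmanr(x, y).statistic)


def _is_normal(x: np.ndarray, alpha: float, max_n: int = 5000,
               seed: int = 0) -> bool:
    if len(x) > max_n:
        x = np.random.default_rng(seed).choice(x, max_n, replace=False)
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue > alpha


def correlation_compare(features_a: pd.DataFrame, features_b: pd.DataFrame,
                        n_boot: int = 2000, seed: int = 0,
                        alpha: float = 0.05) -> CorrelationComparison:
    """Correlation matrices per group, with a bootstrap test per pair on
    the difference of correlation coefficients.

    Pearson is used for a feature pair when all four involved columns pass
    a Shapiro-Wilk normality check (subsampled to 5000) in their group;
    Spearman otherwise. The two-sided bootstrap p-value is twice the
    smaller tail probability of the resampled difference about zero.
    Constant columns yield NaN correlations (flagged by NaN p).
    """
    if list(features_a.columns) != list(features_b.columns):
        raise ValueError("feature columns must match between groups")
    cols = list(features_a.columns)
    k = len(cols)
    rng = np.random.default_rng(seed)
    normal_a = {c: _is_normal(features_a[c].to_numpy(), alpha) for c in cols}
    normal_b = {c: _is_normal(features_b[c].to_numpy(), alpha) for c in cols}
    shape = pd.DataFrame(np.ones((k, k)), index=cols, columns=cols)
    corr_a, corr_b = shape.copy(), shape.copy()
    diff = shape * 0.0
    pvals = shape * 0.0
    method = shape.astype(object)
    stars = shape.astype(object)
    na, nb = len(features_a), len(features_b)
    for i, ci in enumerate(cols):
        method.loc[ci, ci] = "pearson"
        stars.loc[ci, ci] = ""
        pvals.loc[ci, ci] = 1.0
        for cj in cols[i + 1:]:
            use = ("pearson" if all((normal_a[ci], normal_a[cj],
                                     normal_b[ci], normal_b[cj]))
                   else "spearman")
            xa, ya = features_a[ci].to_numpy(), features_a[cj].to_numpy()
            xb, yb = features_b[ci].to_numpy(), features_b[cj].to_numpy()
            constant = np.ptp(xa) == 0 or np.ptp(ya) == 0 \
                or np.ptp(xb) == 0 or np.ptp(yb) == 0
            if constant:
                ra = rb = d = p = np.nan
            else:
                ra, rb = _corr(xa, ya, use), _corr(xb, yb, use)
                d = ra - rb
                draws = np.empty(n_boot)
                for t in range(n_boot):
                    ia = rng.integers(0, na, na)
                    ib = rng.integers(0, nb, nb)
                    if np.ptp(xa[ia]) == 0 or np.ptp(ya[ia]) == 0 \
                            or np.ptp(xb[ib]) == 0 or np.ptp(yb[ib]) == 0:
                        draws[t] = np.nan
                        continue
                    draws[t] = (_corr(xa[ia], ya[ia], use)
                                - _corr(xb[ib], yb[ib], use))
                draws = draws[~np.isnan(draws)]
                lo_tail = (draws <= 0).mean()
                hi_tail = (draws >= 0).mean()
                p = float(min(1.0, 2.0 * min(lo_tail, hi_tail)))
            for (r, c) in ((ci, cj), (cj, ci)):
                corr_a.loc[r, c] = ra
                corr_b.loc[r, c] = rb
                diff.loc[r, c] = d
                pvals.loc[r, c] = p
                method.loc[r, c] = use
                stars.loc[r, c] = "" if np.isnan(p) else _star(p)
    return CorrelationComparison(corr_a=corr_a, corr_b=corr_b, method=method,
                                 difference=diff, p_values=pvals, stars=stars)


# ---------------------------------------------------------------------------
# histogram summaries

@dataclasses.dataclass
class HistogramSummary:
    hist: np.ndarray                  # density-normalized
    bin_edges: np.ndarray
    cumulative: np.ndarray            # ends at 1
    peak: float                       # center of the modal bin
    fwhm: float


def histogram_summary(values: np.ndarray, bins: int = 50) -> HistogramSummary:
    """Normalized histogram with cumulative probability, modal peak and
    full width at half maximum (linear interpolation between bin centers;
    constant data reports one bin and FWHM equal to the bin width)."""
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        v = values[0]
        edges = np.array([v - 0.5, v + 0.5])
        return HistogramSummary(hist=np.array([1.0]), bin_edges=edges,
                                cumulative=np.array([1.0]), peak=float(v),
                                fwhm=1.0)
    hist, edges = np.histogram(values, bins=bins, density=True)
    widths = np.diff(edges)
    cumulative = np.cumsum(hist * widths)
    cumulative /= cumulative[-1]
    centers = (edges[:-1] + edges[1:]) / 2.0
    imax = int(np.argmax(hist))
    half = hist[imax] / 2.0
    # leftward crossing
    left = edges[0]
    for i in range(imax, 0, -1):
        if hist[i - 1] < half <= hist[i]:
            left = np.interp(half, [hist[i - 1], hist[i]],
                             [centers[i - 1], centers[i]])
            break
    right = edges[-1]
    for i in range(imax, len(hist) - 1):
        if hist[i + 1] < half <= hist[i]:
            right = np.interp(half, [hist[i + 1], hist[i]],
                              [centers[i + 1], centers[i]])
            break
    return HistogramSummary(hist=hist, bin_edges=edges, cumulative=cumulative,
                            peak=float(centers[imax]),
                            fwhm=float(right - left))
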
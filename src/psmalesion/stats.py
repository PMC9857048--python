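"""Cohort-level statistics for lesion-response prediction.

Threshold stratification with predictive values and Woolf (logit) odds
ratios, ROC analysis with Youden-index cutoffs oriented for "low uptake
predicts progression", and the rank/paired tests used to compare uptake
distributions between lesion groups and scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import SchemaError, UndefinedStatisticError

__all__ = [
    "OddsRatioResult",
    "odds_ratio_woolf",
    "ThresholdTable",
    "threshold_stratify",
    "RocResult",
    "roc_progression",
    "spearman_rs",
    "mann_whitney_u",
    "paired_t",
]

Z_95 = 1.959963984540054  # two-sided 95 % normal quantile


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    haldane_corrected: bool = False


def odds_ratio_woolf(a: float, b: float, c: float, d: float) -> OddsRatioResult:
    """Odds ratio with a Woolf logit 95 % confidence interval.

    Cell orientation for threshold tables: ``a`` progressive below the
    threshold, ``b`` non-progressive below, ``c`` progressive above,
    ``d`` non-progressive above.  OR = a*d / (b*c); the CI is
    ``exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``.  If any cell is
    zero, 0.5 is added to every cell (Haldane-Anscombe) and the result is
    flagged.  The p-value is the two-sided normal tail of the Woolf z
    statistic ``ln OR / SE``.
    """
    cells = np.asarray([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError(f"cell counts must be non-negative, got {cells.tolist()}")
    if np.all(cells == 0):
        raise UndefinedStatisticError("odds ratio undefined: all four cells are zero")
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    log_or = math.log(or_)
    ci_low = math.exp(log_or - Z_95 * se)
    ci_high = math.exp(log_or + Z_95 * se)
    z = log_or / se
    p = 2.0 * sps.norm.sf(abs(z))
    return OddsRatioResult(or_, ci_low, ci_high, p, haldane_corrected=corrected)


@dataclass(frozen=True)
class ThresholdTable:
    """Lesion response stratified at one tumor-to-liver-ratio cutoff.

    ``counts_below``/``counts_above`` hold (RL, SL, PL) counts for lesions
    with baseline TLR < threshold and >= threshold.  PPV is the progressive
    fraction below the threshold, NPV the non-progressive fraction above;
    both are ``nan`` when the corresponding stratum is empty.
    """

    threshold: float
    counts_below: tuple[int, int, int]
    counts_above: tuple[int, int, int]
    ppv: float
    npv: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    haldane_corrected: bool = False

    @property
    def n_below(self) -> int:
        return int(sum(self.counts_below))

    @property
    def n_above(self) -> int:
        return int(sum(self.counts_above))

    @property
    def n_total(self) -> int:
        return self.n_below + self.n_above


def threshold_stratify(classified: pd.DataFrame, threshold: float) -> ThresholdTable:
    """Split a classified lesion table at one baseline-TLR threshold.

    Lesions with ``tlr_base < threshold`` form the below stratum (test
    positive for predicting progression), the rest the above stratum.
    """
    for col in ("tlr_base", "category"):
        if col not in classified.columns:
            raise SchemaError(f"classified table is missing column {col}")
    tlr = classified["tlr_base"].to_numpy(dtype=float)
    cat = classified["category"].to_numpy()
    if np.any(~np.isfinite(tlr)):
        raise ValueError("tlr_base contains non-finite values")
    below = tlr < threshold

    def counts(mask: np.ndarray) -> tuple[int, int, int]:
        return tuple(int(np.sum(cat[mask] == c)) for c in ("RL", "SL", "PL"))

    cb, ca = counts(below), counts(~below)
    n_below, n_above = sum(cb), sum(ca)
    ppv = cb[2] / n_below if n_below else float("nan")
    npv = (ca[0] + ca[1]) / n_above if n_above else float("nan")
    orr = odds_ratio_woolf(cb[2], cb[0] + cb[1], ca[2], ca[0] + ca[1])
    return ThresholdTable(
        threshold=float(threshold),
        counts_below=cb,
        counts_above=ca,
        ppv=ppv,
        npv=npv,
        odds_ratio=orr.odds_ratio,
        ci_low=orr.ci_low,
        ci_high=orr.ci_high,
        p_value=orr.p_value,
        haldane_corrected=orr.haldane_corrected,
    )


@dataclass(frozen=True)
class RocResult:
    """ROC analysis of a baseline metric for predicting lesion progression."""

    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    curve: pd.DataFrame = field(repr=False)  # columns: cutoff, sensitivity, specificity


def roc_progression(metric: np.ndarray, is_pl: np.ndarray) -> RocResult:
    """ROC of a baseline uptake metric as a predictor of lesion progression.

    Low uptake predicts progression, so the classifier score is the negated
    metric.  The AUC is the tie-corrected pairwise concordance probability
    P(metric_PL < metric_nonPL) + 0.5 * P(equal).  The operating cutoff
    maximizes Youden's J = sensitivity + specificity - 1 over rules of the
    form "call progressive if metric < cutoff", with candidate cutoffs at
    the observed metric values (plus +inf); ties in J resolve toward the
    higher-sensitivity rule.
    """
    metric = np.asarray(metric, dtype=float)
    is_pl = np.asarray(is_pl, dtype=bool)
    if metric.shape != is_pl.shape or metric.ndim != 1:
        raise ValueError("metric and is_pl must be 1D arrays of equal length")
    if not np.all(np.isfinite(metric)):
        raise ValueError("metric contains non-finite values")
    n_pos = int(is_pl.sum())
    n_neg = int((~is_pl).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError("ROC requires both progressive and non-progressive lesions")

    # tie-corrected AUC via mid-ranks of the score (-metric)
    ranks = sps.rankdata(-metric)
    auc = (ranks[is_pl].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    cutoffs = np.concatenate([np.unique(metric), [np.inf]])
    pos = np.sort(metric[is_pl])
    neg = np.sort(metric[~is_pl])
    sens = np.searchsorted(pos, cutoffs, side="left") / n_pos  # P(metric < c | PL)
    spec = 1.0 - np.searchsorted(neg, cutoffs, side="left") / n_neg  # P(metric >= c | not PL)
    j = sens + spec - 1.0
    best_j = j.max()
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    best = candidates[np.argmax(sens[candidates])]
    curve = pd.DataFrame({"cutoff": cutoffs, "sensitivity": sens, "specificity": spec})
    return RocResult(
        auc=float(auc),
        cutoff=float(cutoffs[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        youden_j=float(j[best]),
        curve=curve,
    )


def spearman_rs(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) with its t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1D arrays with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("rank correlation undefined for a constant vector")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; exact for small tie-free samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def paired_t(pre, post) -> tuple[float, float]:
    """Paired two-sided t-test on matched pre/post measurements."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or len(pre) < 2:
        raise ValueError("need equal-length paired 1D samples with n >= 2")
    diff = post - pre
    if np.allclose(diff.std(ddof=1), 0.0):
        raise UndefinedStatisticError("paired t undefined: zero variance of differences")
    res = sps.ttest_rel(post, pre)
    return float(res.statistic), float(res.pvalue)
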
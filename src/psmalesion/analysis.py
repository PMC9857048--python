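"""Cohort-level lesion-response analysis as a model/results pair.

:class:`LesionResponseAnalysis` is built from a lesion table and per-scan
organ references; :meth:`~LesionResponseAnalysis.fit` classifies every
lesion and evaluates the baseline-uptake question — how well do SUV_max,
SUV_mean and the tumor-to-liver ratio predict which lesions will progress
under therapy — returning a :class:`LesionResponseResults` with threshold
tables, ROC analyses, correlations and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as lstats
from .exceptions import UndefinedStatisticError
from .metrics import classify_table, vscore_transition_counts

__all__ = ["LesionResponseAnalysis", "LesionResponseResults"]

DEFAULT_THRESHOLDS = (1.00, 1.50, 1.76, 2.00)
DEFAULT_ROC_METRICS = ("suvmax_base", "suvmean_base", "tlr_base")


class LesionResponseAnalysis:
    """Lesion-response analysis of a paired baseline/post-therapy cohort.

    Parameters
    ----------
    lesions
        Per-lesion table with the standard columns (``patient_id, lesion_id,
        site, suvmax_base, suvmean_base, suvmax_post, suvmean_post``).
    references
        Per-scan organ references (``patient_id, timepoint, blood_pool,
        liver_mean, parotid``).
    thresholds
        Baseline-TLR cutoffs at which to stratify lesion response.
    roc_metrics
        Baseline columns to evaluate as predictors of progression.
    """

    def __init__(
        self,
        lesions: pd.DataFrame,
        references: pd.DataFrame,
        thresholds=DEFAULT_THRESHOLDS,
        roc_metrics=DEFAULT_ROC_METRICS,
    ) -> None:
        self.lesions = lesions
        self.references = references
        self.thresholds = tuple(float(t) for t in thresholds)
        self.roc_metrics = tuple(roc_metrics)

    @classmethod
    def from_csv(cls, lesions_path, references_path, **kwargs) -> "LesionResponseAnalysis":
        return cls(pd.read_csv(lesions_path), pd.read_csv(references_path), **kwargs)

    def fit(self) -> "LesionResponseResults":
        classified, excluded = classify_table(self.lesions, self.references)

        threshold_tables = {
            t: lstats.threshold_stratify(classified, t) for t in self.thresholds
        }

        roc: dict[str, lstats.RocResult] = {}
        is_pl = (classified["category"] == "PL").to_numpy()
        for metric in self.roc_metrics:
            values = classified[metric].to_numpy(dtype=float)
            try:
                roc[metric] = lstats.roc_progression(values, is_pl)
            except UndefinedStatisticError:
                continue  # single-class cohort: ROC undefined for every metric

        # Association of baseline uptake with response depth: rank correlation
        # between the baseline metric and the percent SUV_max *decline*.
        correlations: dict[str, tuple[float, float]] = {}
        decline = -classified["delta_pct"].to_numpy(dtype=float)
        ok = np.isfinite(decline)
        for metric in self.roc_metrics:
            values = classified[metric].to_numpy(dtype=float)
            if ok.sum() >= 3 and np.ptp(values[ok]) > 0 and np.ptp(decline[ok]) > 0:
                correlations[metric] = lstats.spearman_rs(values[ok], decline[ok])

        liver_ttest = self._liver_stability_test()
        transitions = vscore_transition_counts(classified)

        return LesionResponseResults(
            model=self,
            classified=classified,
            excluded=excluded,
            threshold_tables=threshold_tables,
            roc=roc,
            correlations=correlations,
            liver_ttest=liver_ttest,
            vscore_transitions=transitions,
        )

    def _liver_stability_test(self):
        """Paired t of per-patient liver SUV_mean, baseline vs post-therapy."""
        wide = self.references.pivot_table(
            index="patient_id", columns="timepoint", values="liver_mean", aggfunc="first"
        )
        if not {"base", "post"}.issubset(wide.columns):
            return None
        wide = wide.dropna(subset=["base", "post"])
        if len(wide) < 2:
            return None
        try:
            t, p = lstats.paired_t(wide["base"].to_numpy(), wide["post"].to_numpy())
        except UndefinedStatisticError:
            return None
        return {
            "n_patients": int(len(wide)),
            "mean_base": float(wide["base"].mean()),
            "mean_post": float(wide["post"].mean()),
            "t": t,
            "p": p,
        }


@dataclass
class LesionResponseResults:
    """Fitted lesion-response analysis.

    Attributes
    ----------
    classified
        The lesion table annotated with TLR, V-scores, percent change and
        RL/SL/PL category.
    excluded
        Rows dropped before analysis, with a ``reason`` column.
    threshold_tables
        :class:`~psmalesion.stats.ThresholdTable` per requested TLR cutoff.
    roc
        :class:`~psmalesion.stats.RocResult` per baseline metric.
    correlations
        ``metric -> (rs, p)`` Spearman correlation of baseline uptake with
        percent SUV_max decline.
    liver_ttest
        Paired t-test of per-patient liver reference uptake (or None).
    vscore_transitions
        4x4 baseline-to-post V-score count matrix.
    """

    model: LesionResponseAnalysis
    classified: pd.DataFrame
    excluded: pd.DataFrame
    threshold_tables: dict[float, lstats.ThresholdTable]
    roc: dict[str, lstats.RocResult]
    correlations: dict[str, tuple[float, float]]
    liver_ttest: dict | None
    vscore_transitions: pd.DataFrame

    @property
    def category_counts(self) -> dict[str, int]:
        vc = self.classified["category"].value_counts()
        return {c: int(vc.get(c, 0)) for c in ("RL", "SL", "PL")}

    def threshold_frame(self) -> pd.DataFrame:
        """Threshold tables as one DataFrame (one row per cutoff)."""
        rows = []
        for t, tab in sorted(self.threshold_tables.items()):
            rows.append(
                {
                    "threshold": t,
                    "n_below": tab.n_below,
                    "rl_below": tab.counts_below[0],
                    "sl_below": tab.counts_below[1],
                    "pl_below": tab.counts_below[2],
                    "n_above": tab.n_above,
                    "rl_above": tab.counts_above[0],
                    "sl_above": tab.counts_above[1],
                    "pl_above": tab.counts_above[2],
                    "ppv_pct": _pct(tab.ppv),
                    "npv_pct": _pct(tab.npv),
                    "or_display": f"{tab.odds_ratio:.2f} ({tab.ci_low:.2f}-{tab.ci_high:.2f})",
                    "ppv": tab.ppv,
                    "npv": tab.npv,
                    "odds_ratio": tab.odds_ratio,
                    "ci_low": tab.ci_low,
                    "ci_high": tab.ci_high,
                    "p_value": tab.p_value,
                    "haldane_corrected": tab.haldane_corrected,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report of the fitted analysis."""
        counts = self.category_counts
        n = len(self.classified)
        lines = [
            "Lesion response analysis",
            "=" * 64,
            f"lesions analyzed: {n}   excluded: {len(self.excluded)}",
            "response categories: "
            + "  ".join(f"{c} {counts[c]} ({_pct(counts[c] / n) if n else '-'}%)" for c in counts),
            "",
            "TLR threshold stratification (PPV/NPV for progression):",
        ]
        for t, tab in sorted(self.threshold_tables.items()):
            lines.append(
                f"  TLR {t:<5.2f} below n={tab.n_below:<4d} PPV {_pct(tab.ppv)}%  "
                f"NPV {_pct(tab.npv)}%  OR {tab.odds_ratio:.2f} "
                f"({tab.ci_low:.2f}-{tab.ci_high:.2f})"
            )
        if self.roc:
            lines.append("")
            lines.append("ROC for progression (low baseline uptake predicts PL):")
            for metric, r in self.roc.items():
                lines.append(
                    f"  {metric:<14s} AUC {r.auc:.2f}  cutoff {r.cutoff:.2f} "
                    f"(sens {r.sensitivity * 100:.0f}%, spec {r.specificity * 100:.0f}%)"
                )
        if self.correlations:
            lines.append("")
            lines.append("Spearman rs, baseline metric vs percent SUV_max decline:")
            for metric, (rs, p) in self.correlations.items():
                lines.append(f"  {metric:<14s} rs = {rs:+.2f}  (p = {p:.3g})")
        if self.liver_ttest is not None:
            lt = self.liver_ttest
            lines.append("")
            lines.append(
                f"liver reference stability (paired t, n={lt['n_patients']}): "
                f"{lt['mean_base']:.2f} vs {lt['mean_post']:.2f}, p = {lt['p']:.2g}"
            )
        return "\n".join(lines)


def _pct(x: float) -> str:
    """Whole-number percentage for display; '-' when undefined."""
    if x is None or not np.isfinite(x):
        return "-"
    return str(round(100 * x))
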
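"""Cohort summarization and end-to-end report bundles.

``summarize_cohort`` condenses a classified lesion table into the shape of
a baseline-characteristics table: per-site lesion counts, median (IQR) of
SUV_max / SUV_mean / TLR overall and stratified by response category, and
the baseline V-score distribution.  ``run_pipeline`` orchestrates a full
run — synthetic generation or user CSVs, classification, threshold and ROC
statistics — and writes a self-consistent report bundle.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import DEFAULT_ROC_METRICS, DEFAULT_THRESHOLDS, LesionResponseAnalysis
from .exceptions import SchemaError
from .metrics import CATEGORIES
from .simulate import SyntheticCohortConfig, generate_cohort

__all__ = ["CohortSummary", "summarize_cohort", "run_pipeline"]

_METRIC_COLS = ("suvmax_base", "suvmean_base", "tlr_base")


def _median_iqr(values: pd.Series) -> tuple[float, float, float]:
    """Median and (Q1, Q3) with linear-interpolation quantiles; NaN if empty."""
    v = values.dropna().to_numpy(dtype=float)
    if v.size == 0:
        return (float("nan"),) * 3
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return float(med), float(q1), float(q3)


@dataclass
class CohortSummary:
    """Baseline characteristics of a classified lesion cohort."""

    n_total: int
    category_counts: dict[str, int]
    site_table: pd.DataFrame
    response_table: pd.DataFrame
    vscore_base_counts: dict[int, int]

    @property
    def category_pct(self) -> dict[str, int]:
        """Whole-number category percentages (of classified lesions)."""
        if self.n_total == 0:
            return {c: 0 for c in CATEGORIES}
        return {c: round(100 * n / self.n_total) for c, n in self.category_counts.items()}

    def render(self) -> str:
        """Plain-text rendering; empty cells print as '-' (never 0)."""
        def cell(med, q1, q3, n):
            if not np.isfinite(med):
                return "-"
            if n == 1:
                return f"{med:.2f}"
            return f"{med:.2f} ({q1:.2f}-{q3:.2f})"

        lines = ["Baseline lesion characteristics", "=" * 64]
        for _, row in self.site_table.iterrows():
            lines.append(
                f"{row['site']:<14s} n={int(row['n']):<4d} "
                f"SUVmax {cell(row['suvmax_base_median'], row['suvmax_base_q1'], row['suvmax_base_q3'], row['n'])}  "
                f"TLR {cell(row['tlr_base_median'], row['tlr_base_q1'], row['tlr_base_q3'], row['n'])}"
            )
        lines.append("")
        lines.append("Response categories by site (n (%)):")
        for site in self.site_table["site"]:
            sub = self.response_table[self.response_table["site"] == site]
            total = int(self.site_table.loc[self.site_table["site"] == site, "n"].iloc[0])
            parts = []
            for cat in CATEGORIES:
                r = sub[sub["category"] == cat]
                n = int(r["n"].iloc[0]) if len(r) else 0
                pct = round(100 * n / total) if total else 0
                parts.append(f"{cat} {n} ({pct})")
            lines.append(f"{site:<14s} " + "  ".join(parts))
        lines.append("")
        vs = "  ".join(f"V{k}: {v}" for k, v in sorted(self.vscore_base_counts.items()))
        lines.append(f"baseline V-score counts: {vs}")
        return "\n".join(lines)


def summarize_cohort(classified: pd.DataFrame) -> CohortSummary:
    """Summarize a classified lesion table per site and response category."""
    required = {"site", "category", *_METRIC_COLS, "vscore_base"}
    missing = sorted(required - set(classified.columns))
    if missing:
        raise SchemaError(f"classified table is missing columns: {missing}")

    sites = list(dict.fromkeys(classified["site"])) + ["all"]
    site_rows = []
    response_rows = []
    for site in sites:
        sub = classified if site == "all" else classified[classified["site"] == site]
        row = {"site": site, "n": len(sub)}
        for col in _METRIC_COLS:
            med, q1, q3 = _median_iqr(sub[col])
            row[f"{col}_median"], row[f"{col}_q1"], row[f"{col}_q3"] = med, q1, q3
        site_rows.append(row)
        for cat in CATEGORIES:
            csub = sub[sub["category"] == cat]
            crow = {"site": site, "category": cat, "n": len(csub)}
            crow["pct"] = 100 * len(csub) / len(sub) if len(sub) else float("nan")
            for col in _METRIC_COLS:
                med, q1, q3 = _median_iqr(csub[col])
                crow[f"{col}_median"], crow[f"{col}_q1"], crow[f"{col}_q3"] = med, q1, q3
            response_rows.append(crow)

    vc = classified["category"].value_counts()
    vscounts = classified["vscore_base"].value_counts()
    return CohortSummary(
        n_total=len(classified),
        category_counts={c: int(vc.get(c, 0)) for c in CATEGORIES},
        site_table=pd.DataFrame(site_rows),
        response_table=pd.DataFrame(response_rows),
        vscore_base_counts={k: int(vscounts.get(k, 0)) for k in (0, 1, 2, 3)},
    )


def run_pipeline(
    out_dir,
    config: SyntheticCohortConfig | None = None,
    lesions: pd.DataFrame | None = None,
    references: pd.DataFrame | None = None,
    thresholds=DEFAULT_THRESHOLDS,
    roc_metrics=DEFAULT_ROC_METRICS,
    log_stream=None,
):
    """Run the full analysis and write a report bundle to ``out_dir``.

    Either a :class:`SyntheticCohortConfig` (synthetic run) or a lesion +
    reference table pair must be supplied.  The bundle contains the input
    and classified tables, the summary, the threshold TSV (omitted when
    ``thresholds`` is empty), one ROC TSV per metric, the V-score transition
    matrix, and a JSON run log with the seed and package versions.  On
    failure every partially written file is removed.

    Returns the fitted :class:`~psmalesion.analysis.LesionResponseResults`.
    """
    if (config is None) == (lesions is None and references is None):
        if config is None:
            raise ValueError("supply either a config or lesion+reference tables")
    if config is not None:
        lesions, references = generate_cohort(config)
    if lesions is None or references is None:
        raise ValueError("both lesion and reference tables are required")

    model = LesionResponseAnalysis(
        lesions, references, thresholds=thresholds, roc_metrics=roc_metrics
    )
    results = model.fit()
    summary = summarize_cohort(results.classified)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log = log_stream if log_stream is not None else sys.stderr

    def _write(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        print(f"[psmalesion] wrote {path}", file=log)
        return path

    try:
        if config is not None:
            _write("config.json", lambda p: Path(p).write_text(config.to_json() + "\n"))
            _write("lesions.csv", lambda p: lesions.to_csv(p, index=False))
            _write("references.csv", lambda p: references.to_csv(p, index=False))
        _write("classified.csv", lambda p: results.classified.to_csv(p, index=False))
        if len(results.excluded):
            _write("excluded.csv", lambda p: results.excluded.to_csv(p, index=False))
        _write("summary.txt", lambda p: Path(p).write_text(summary.render() + "\n"))
        _write(
            "summary_sites.csv", lambda p: summary.site_table.to_csv(p, index=False)
        )
        _write(
            "summary_response.csv",
            lambda p: summary.response_table.to_csv(p, index=False),
        )
        if thresholds:
            _write(
                "thresholds.tsv",
                lambda p: results.threshold_frame().to_csv(p, sep="\t", index=False),
            )
        for metric, roc in results.roc.items():
            frame = roc.curve.assign(auc=roc.auc, best_cutoff=roc.cutoff)
            _write(
                f"roc_{metric}.tsv", lambda p, f=frame: f.to_csv(p, sep="\t", index=False)
            )
        _write(
            "vscore_transitions.tsv",
            lambda p: results.vscore_transitions.to_csv(p, sep="\t"),
        )
        _write("report.txt", lambda p: Path(p).write_text(results.summary() + "\n"))

        import psmalesion

        run_log = {
            "seed": config.seed if config is not None else None,
            "synthetic": config is not None,
            "n_lesions_input": int(len(lesions)),
            "n_classified": int(len(results.classified)),
            "n_excluded": int(len(results.excluded)),
            "thresholds": list(thresholds),
            "roc_metrics": list(roc_metrics),
            "versions": {
                "psmalesion": psmalesion.__version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        _write("run_log.json", lambda p: Path(p).write_text(json.dumps(run_log, indent=2) + "\n"))
    except BaseException:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return results
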
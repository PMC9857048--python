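"""Per-lesion derived metrics and response classification.

Encodes the lesion-level reading rules used in PSMA radioligand-therapy
response assessment:

* **TLR** — tumor-to-liver ratio, lesion SUV_max divided by the mean liver
  uptake of the same scan.
* **V-score** — the E-PSMA 4-point visual scale against blood pool, liver
  and parotid landmarks: 0 below blood pool; 1 above blood pool but at or
  below liver; 2 above liver but at or below parotid; 3 above parotid.
* **RL / SL / PL** — responding (SUV_max decline >= 30 % *or* post-therapy
  V-score 0), stable (|change| < 30 %) and progressive (increase >= 30 %)
  lesions.  Both 30 % boundaries are inclusive, and a post-therapy V-score
  of 0 forces RL regardless of the percent change (the response definition
  is a disjunction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ReferenceUptakeError, SchemaError, UndefinedStatisticError

__all__ = [
    "ScanReference",
    "pct_change",
    "compute_tlr",
    "assign_vscore",
    "classify_response",
    "classify_table",
    "vscore_transition_counts",
    "CATEGORIES",
]

CATEGORIES = ("RL", "SL", "PL")

#: Inclusive percent-change boundary separating response/progression.
RESPONSE_DECLINE_PCT = -30.0
PROGRESSION_RISE_PCT = 30.0


@dataclass(frozen=True)
class ScanReference:
    """Organ reference uptakes for one patient-scan."""

    patient_id: str
    timepoint: str  # "base" or "post"
    blood_pool: float
    liver_mean: float
    parotid: float

    def __post_init__(self) -> None:
        if self.timepoint not in ("base", "post"):
            raise ValueError(f"timepoint must be 'base' or 'post', got {self.timepoint!r}")
        if not 0 < self.blood_pool < self.parotid:
            raise ReferenceUptakeError(
                f"need 0 < blood_pool < parotid, got {self.blood_pool} / {self.parotid}"
            )
        if self.liver_mean <= 0:
            raise ReferenceUptakeError(f"liver_mean must be positive, got {self.liver_mean}")


def pct_change(base: float, post: float) -> float:
    """Percent change of an uptake value, 100 * (post - base) / base."""
    if base <= 0:
        raise UndefinedStatisticError(f"percent change undefined for base={base}")
    return 100.0 * (post - base) / base


def compute_tlr(suvmax: float, liver_mean: float) -> float:
    """Tumor-to-liver ratio: SUV_max / liver SUV_mean."""
    if liver_mean <= 0:
        raise ReferenceUptakeError(f"liver_mean must be positive, got {liver_mean}")
    return suvmax / liver_mean


def assign_vscore(lesion_suv: float, ref: ScanReference) -> int:
    """E-PSMA visual score of a lesion against one scan's organ landmarks.

    Score 0 requires uptake strictly below the blood pool; a lesion exactly
    at the blood pool scores 1.
    """
    if lesion_suv < ref.blood_pool:
        return 0
    if lesion_suv <= ref.liver_mean:
        return 1
    if lesion_suv <= ref.parotid:
        return 2
    return 3


def classify_response(delta_pct: float, vscore_post: int) -> str:
    """RL/SL/PL category from percent SUV_max change and post-therapy V-score.

    RL if the decline reaches 30 % or the lesion falls below the blood pool
    (V-score 0); otherwise PL if the increase reaches 30 %; otherwise SL.
    """
    if not np.isfinite(delta_pct):
        raise UndefinedStatisticError("delta_pct must be finite")
    if vscore_post not in (0, 1, 2, 3):
        raise ValueError(f"vscore_post must be in 0..3, got {vscore_post}")
    if delta_pct <= RESPONSE_DECLINE_PCT or vscore_post == 0:
        return "RL"
    if delta_pct >= PROGRESSION_RISE_PCT:
        return "PL"
    return "SL"


_REQUIRED_LESION_COLS = [
    "patient_id",
    "lesion_id",
    "site",
    "suvmax_base",
    "suvmean_base",
    "suvmax_post",
    "suvmean_post",
]


def _reference_lookup(references: pd.DataFrame) -> dict[tuple[str, str], ScanReference]:
    missing = [c for c in ("patient_id", "timepoint", "blood_pool", "liver_mean", "parotid")
               if c not in references.columns]
    if missing:
        raise SchemaError(f"reference table is missing columns: {missing}")
    lookup = {}
    for rec in references.itertuples(index=False):
        lookup[(rec.patient_id, rec.timepoint)] = ScanReference(
            patient_id=rec.patient_id,
            timepoint=rec.timepoint,
            blood_pool=float(rec.blood_pool),
            liver_mean=float(rec.liver_mean),
            parotid=float(rec.parotid),
        )
    return lookup


def classify_table(
    lesions: pd.DataFrame, references: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute per-lesion metrics and response categories for a cohort table.

    Adds the columns ``tlr_base, tlr_post, vscore_base, vscore_post,
    delta_pct, category`` to a copy of ``lesions``.  Post-treatment TLR uses
    the post-scan liver mean.  Lesions with missing post-treatment SUV_max
    are excluded from the classified table and returned separately with the
    exclusion reason — they are never silently dropped.

    Returns
    -------
    classified, excluded : DataFrame
        The annotated table and the excluded rows (with a ``reason`` column).
    """
    missing = [c for c in _REQUIRED_LESION_COLS if c not in lesions.columns]
    if missing:
        raise SchemaError(f"lesion table is missing columns: {missing}")
    refs = _reference_lookup(references)

    out = lesions.copy()
    excluded_idx: list[int] = []
    reasons: list[str] = []
    tlr_base = np.full(len(out), np.nan)
    tlr_post = np.full(len(out), np.nan)
    vs_base = np.full(len(out), -1, dtype=int)
    vs_post = np.full(len(out), -1, dtype=int)
    delta = np.full(len(out), np.nan)
    category = np.array([""] * len(out), dtype=object)

    for i, rec in enumerate(out.itertuples(index=False)):
        ref_b = refs.get((rec.patient_id, "base"))
        ref_p = refs.get((rec.patient_id, "post"))
        if ref_b is None or ref_p is None:
            excluded_idx.append(i)
            reasons.append(f"missing {'base' if ref_b is None else 'post'} scan reference")
            continue
        if pd.isna(rec.suvmax_post):
            # A lesion no longer measurable post-therapy counts as responding
            # (V-score 0) only when the analyst/generator flagged it so.
            if bool(getattr(rec, "post_undetectable", False)):
                if pd.isna(rec.suvmax_base) or rec.suvmax_base <= 0:
                    excluded_idx.append(i)
                    reasons.append("missing or non-positive baseline SUV_max")
                    continue
                tlr_base[i] = compute_tlr(rec.suvmax_base, ref_b.liver_mean)
                vs_base[i] = assign_vscore(rec.suvmax_base, ref_b)
                vs_post[i] = 0
                category[i] = "RL"
                continue
            excluded_idx.append(i)
            reasons.append("missing post-treatment SUV_max")
            continue
        if pd.isna(rec.suvmax_base) or rec.suvmax_base <= 0:
            excluded_idx.append(i)
            reasons.append("missing or non-positive baseline SUV_max")
            continue
        tlr_base[i] = compute_tlr(rec.suvmax_base, ref_b.liver_mean)
        tlr_post[i] = compute_tlr(rec.suvmax_post, ref_p.liver_mean)
        vs_base[i] = assign_vscore(rec.suvmax_base, ref_b)
        vs_post[i] = assign_vscore(rec.suvmax_post, ref_p)
        delta[i] = pct_change(rec.suvmax_base, rec.suvmax_post)
        category[i] = classify_response(delta[i], vs_post[i])

    out["tlr_base"] = tlr_base
    out["tlr_post"] = tlr_post
    out["vscore_base"] = vs_base
    out["vscore_post"] = vs_post
    out["delta_pct"] = delta
    out["category"] = category

    excluded = out.iloc[excluded_idx].copy()
    excluded["reason"] = reasons
    classified = out.drop(out.index[excluded_idx]).reset_index(drop=True)
    return classified, excluded


def vscore_transition_counts(classified: pd.DataFrame) -> pd.DataFrame:
    """4x4 matrix of lesion counts moving from baseline to post-therapy V-score.

    Entry (i, j) counts lesions with baseline score i and post-therapy score
    j; the grand total equals the number of lesions carrying both scores.
    """
    for col in ("vscore_base", "vscore_post"):
        if col not in classified.columns:
            raise SchemaError(f"classified table is missing column {col}")
    ok = classified[["vscore_base", "vscore_post"]].isin([0, 1, 2, 3]).all(axis=1)
    sub = classified.loc[ok]
    mat = np.zeros((4, 4), dtype=int)
    for b, p in zip(sub["vscore_base"].astype(int), sub["vscore_post"].astype(int)):
        mat[b, p] += 1
    idx = pd.Index([0, 1, 2, 3], name="vscore_base")
    cols = pd.Index([0, 1, 2, 3], name="vscore_post")
    return pd.DataFrame(mat, index=idx, columns=cols)
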
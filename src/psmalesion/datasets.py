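"""Built-in synthetic example data.

``synthetic_reference_cohort`` expands published *aggregate* counts from a
718-lesion mCRPC radioligand-therapy cohort into a synthetic per-lesion
table: the response-category totals per site, and the response counts in
nested baseline tumor-to-liver-ratio (TLR) strata at cutoffs
1.00/1.50/1.76/2.00.  Only those counts are real; per-lesion SUV values are
stratum-consistent placeholders (one representative TLR per stratum, liver
reference fixed at 4.1), so the table reproduces the published stratified
statistics exactly while carrying no per-lesion clinical information.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["synthetic_reference_cohort", "STRATUM_COUNTS", "SITE_CATEGORY_COUNTS"]

#: (RL, SL, PL) counts per baseline-TLR stratum, derived by differencing the
#: nested below-threshold counts at cutoffs 1.00 / 1.50 / 1.76 / 2.00.
STRATUM_COUNTS: dict[tuple[float, float | None], tuple[int, int, int]] = {
    (0.0, 1.00): (19, 9, 14),
    (1.00, 1.50): (45, 21, 15),
    (1.50, 1.76): (21, 5, 6),
    (1.76, 2.00): (20, 7, 1),
    (2.00, None): (445, 79, 11),
}

#: Representative TLR placed at every lesion of a stratum (strictly inside it).
_STRATUM_TLR = {
    (0.0, 1.00): 0.70,
    (1.00, 1.50): 1.20,
    (1.50, 1.76): 1.60,
    (1.76, 2.00): 1.85,
    (2.00, None): 3.36,
}

#: (RL, SL, PL) counts per metastatic site.
SITE_CATEGORY_COUNTS: dict[str, tuple[int, int, int]] = {
    "bone": (389, 84, 34),
    "lymph_node": (143, 29, 9),
    "visceral": (12, 7, 3),
    "primary": (6, 1, 1),
}

_LIVER = 4.1
_BLOOD = 1.8
_PAROTID = 15.0
_SUVMEAN_FRACTION = 0.62
#: Post/baseline SUV_max multiplier applied per category (placeholder change).
_CHANGE = {"RL": 0.5, "SL": 1.0, "PL": 1.5}


def synthetic_reference_cohort() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic per-lesion expansion of the published aggregate counts.

    Returns a ``(lesions, references)`` pair in the standard table dialect,
    all lesions under one pseudo-patient with liver SUV_mean 4.1 at both
    timepoints.  Classifying this table recovers the published site and
    stratum counts exactly; medians/IQRs of the SUV columns are artifacts
    of the placeholder values and carry no meaning.
    """
    sites: dict[str, list[str]] = {}
    for cat_idx, cat in enumerate(("RL", "SL", "PL")):
        labels: list[str] = []
        for site, counts in SITE_CATEGORY_COUNTS.items():
            labels.extend([site] * counts[cat_idx])
        sites[cat] = labels

    rows = []
    cursor = {"RL": 0, "SL": 0, "PL": 0}
    lesion_no = 0
    for stratum, counts in STRATUM_COUNTS.items():
        tlr = _STRATUM_TLR[stratum]
        suvmax = tlr * _LIVER
        for cat, n in zip(("RL", "SL", "PL"), counts):
            for _ in range(n):
                lesion_no += 1
                site = sites[cat][cursor[cat]]
                cursor[cat] += 1
                post = suvmax * _CHANGE[cat]
                rows.append(
                    {
                        "patient_id": "COHORT",
                        "lesion_id": f"COHORT-L{lesion_no:03d}",
                        "site": site,
                        "suvmax_base": suvmax,
                        "suvmean_base": suvmax * _SUVMEAN_FRACTION,
                        "suvmax_post": post,
                        "suvmean_post": post * _SUVMEAN_FRACTION,
                    }
                )
    lesions = pd.DataFrame(rows)
    references = pd.DataFrame(
        [
            {
                "patient_id": "COHORT",
                "timepoint": tp,
                "blood_pool": _BLOOD,
                "liver_mean": _LIVER,
                "parotid": _PAROTID,
            }
            for tp in ("base", "post")
        ]
    )
    return lesions, references
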
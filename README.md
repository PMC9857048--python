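# psmalesion

Lesion-based response analysis for PSMA-targeted PET/CT around
[<sup>177</sup>Lu]Lu-PSMA-617 radioligand therapy (RLT) in metastatic
castration-resistant prostate cancer.

Patient selection for RLT conventionally requires lesion uptake on
[<sup>68</sup>Ga]Ga-PSMA-11 PET to exceed the liver, yet it has been unclear
how lesions *below* liver-derived uptake thresholds actually fare under
therapy. This package provides the full per-lesion analysis chain needed to
study that question — for nuclear-medicine researchers quantifying paired
PET scans, and for methodologists who want the statistical machinery with a
synthetic cohort standing in for clinical data:

- **Quantification** (`psmalesion.uptake`) — SUV_max/SUV_mean inside a 40 %
  fractional isocontour (26-connected component around the peak), and the
  30 mm spherical liver reference VOI, on axis-aligned NIfTI volumes.
- **Per-lesion metrics** (`psmalesion.metrics`) — tumor-to-liver ratio
  TLR = SUV_max / SUV_mean(liver); the E-PSMA 4-point visual score
  (0 below blood pool, 1 ≤ liver, 2 ≤ parotid, 3 above parotid); response
  category RL / SL / PL (responding: ΔSUV_max ≤ −30 % or post-therapy
  V-score 0; progressive: ΔSUV_max ≥ +30 %; stable otherwise).
- **Cohort statistics** (`psmalesion.stats`, `psmalesion.analysis`) —
  threshold stratification with PPV/NPV and Woolf logit odds ratios
  (OR = ad/bc, CI = exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))), ROC/AUC with
  Youden-index cutoffs oriented "progressive if metric < cutoff", Spearman
  rank correlation, Mann–Whitney U and paired t tests.
- **Synthetic data** (`psmalesion.simulate`) — cohort generator with a
  continuation-ratio logistic response model in log TLR, and sphere/liver
  PET phantoms with Gaussian PSF and noise for exercising the quantifier.
- **Reporting** (`psmalesion.report`, CLI `psmalesion`) — cohort summary
  tables, threshold/ROC TSVs, V-score transition matrices, reproducible
  report bundles.

## Worked example

```python
from psmalesion import LesionResponseAnalysis, SyntheticCohortConfig, generate_cohort

config = SyntheticCohortConfig(n_patients=20, seed=42)
lesions, references = generate_cohort(config)
results = LesionResponseAnalysis(lesions, references).fit()
print(results.summary())
```

```
Lesion response analysis
================================================================
lesions analyzed: 265   excluded: 0
response categories: RL 200 (75%)  SL 46 (17%)  PL 19 (7%)

TLR threshold stratification (PPV/NPV for progression):
  TLR 1.00  below n=10   PPV 20%  NPV 93%  OR 3.50 (0.69-17.79)
  TLR 1.50  below n=37   PPV 14%  NPV 94%  OR 2.39 (0.81-7.08)
  TLR 1.76  below n=48   PPV 19%  NPV 95%  OR 4.78 (1.82-12.52)
  TLR 2.00  below n=63   PPV 16%  NPV 96%  OR 4.05 (1.56-10.47)

ROC for progression (low baseline uptake predicts PL):
  suvmax_base    AUC 0.74  cutoff 9.71 (sens 74%, spec 73%)
  suvmean_base   AUC 0.73  cutoff 6.19 (sens 74%, spec 71%)
  tlr_base       AUC 0.74  cutoff 2.73 (sens 79%, spec 67%)

Spearman rs, baseline metric vs percent SUV_max decline:
  suvmax_base    rs = +0.24  (p = 6.13e-05)
  suvmean_base   rs = +0.25  (p = 3.99e-05)
  tlr_base       rs = +0.26  (p = 2.26e-05)

liver reference stability (paired t, n=20): 4.12 vs 4.09, p = 0.79
```

Reading the output: three quarters of the simulated lesions respond to
therapy, and among low-uptake lesions (TLR below a liver-based cutoff) only
a minority progress — the PPV of a "below liver" rule for flagging
refractory lesions is modest even though its odds ratio is clearly above 1,
while the NPV is high: lesions above the cutoff almost never progress.
ROC AUCs near 0.75 say baseline uptake separates future progressors
moderately well in this cohort; the positive Spearman rs confirms that
hotter lesions tend to show deeper SUV_max declines. The paired t-test
checks that the liver reference itself stayed stable between scans, which
underpins using liver-normalized ratios at both timepoints.

The same analysis runs from the shell:

```bash
psmalesion report --seed 42 --out-dir out/           # synthetic end-to-end run
psmalesion simulate --seed 7 --out-dir sim/          # just the cohort tables
psmalesion classify --lesions sim/lesions.csv --references sim/references.csv \
    --out classified.csv
psmalesion thresholds --classified classified.csv --thresholds 1.0,1.5,1.76,2.0 \
    --out thresholds.tsv
psmalesion roc --classified classified.csv --metric tlr_base --out roc.tsv
```

`psmalesion.datasets.synthetic_reference_cohort()` provides a built-in
718-lesion table expanded from published aggregate counts of a real RLT
cohort (category totals per site and per nested TLR stratum; per-lesion SUVs
are synthetic placeholders), useful for validating the stratified statistics
against known values.

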
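# primarysite

Tissue-of-origin classification for whole-genome sequenced tumors, built for
the cancer-of-unknown-primary (CUP) setting: ~3% of cancer diagnoses are
metastases whose primary site cannot be determined by routine
histopathology, which directly limits treatment options. Given a tumor's
somatic mutation calls, `primarysite` derives genome-wide features —
mutational-signature exposures over the SBS96/DBS78/ID83 context schemes,
regional mutational density (RMD) profiles over megabase bins, chromosome-arm
copy-number fold changes, driver/fusion/viral-insertion events and
structural-variant burdens — and classifies the tumor's tissue of origin
with a calibrated one-vs-rest random-forest ensemble. Every prediction comes
with a per-feature explanation and a patient-level report, so the output can
be audited against domain knowledge rather than trusted blindly.

The intended users are cancer-genomics researchers and bioinformaticians
with access to somatic variant calls (point mutations, copy-number segments,
SV clusters and annotated driver/fusion/viral events).

## The model

For each cancer type *c*, a binary random forest is trained case-vs-rest:

- **Feature selection.** Numeric features are tested with Wilcoxon rank-sum
  and scored by Cliff's delta; boolean features with Fisher's exact test and
  Cramér's V; keep *p* < 0.01 and effect ≥ 0.1, capped at the best 100.
- **Class balancing.** With *n₁* cases and *n₀* controls, candidate
  oversampling targets are log-spaced from *n₁* to g = √(n₁n₀) and
  undersampling targets from *n₀* down to g; the 5×5 grid is searched by
  mean area under the precision-recall curve (AUPRC) in stratified 10-fold
  cross-validation, resampling training folds only.
- **RMD profiles.** Raw 1 Mb RMD bins are compressed per class by
  KL-divergence NMF with a masked-imputation rank search (ranks 1–10, 50
  runs, 10% of entries held out; the chosen rank precedes the first > 0.2%
  rise in log₁₀ median imputation MSE), then deduplicated across classes by
  complete-linkage clustering on 1 − Pearson correlation cut at 0.1.
  Samples are fitted to the final profiles by non-negative least squares.
- **Calibration.** The full per-class procedure is rerun in stratified
  15-fold cross-validation; the out-of-fold probabilities train one
  isotonic regression per class, making probabilities comparable across
  forests (a calibrated 0.8 means ≈80% chance of being correct).
- **Gender filter.** Breast/ovarian/cervix probabilities are zeroed for
  males, prostate for females, before and after calibration.
- **Explanations.** Local increments: along each tree path the change in
  node positive-class fraction at a split is credited to the split feature;
  baseline + Σ contributions reconstructs the forest probability exactly.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Train and evaluate on a synthetic cohort (no external data needed — the
package ships a generator that plants class-specific RMD profiles,
signature mixtures, marker prevalences and gender constraints):

```bash
primarysite simulate --classes 8 --samples-per-class 150 --seed 11 --out cohort/
primarysite train --features cohort/features.tsv --labels cohort/truth.tsv \
    --desk-scale --seed 37 --out model/
primarysite predict --model model/ --features cohort/features.tsv \
    --out predictions.tsv
primarysite evaluate --truth cohort/truth.tsv --probs predictions.tsv --out perf
```

The evaluate step prints:

```
micro recall 1.000, top-2 1.000, precision 1.000
```

i.e. on this cleanly separable training cohort every sample's highest
calibrated probability is its true class (real cohorts are far harder; the
held-out-split behaviour is exercised in `tests/test_acceptance.py`). A
patient report for one sample:

```bash
primarysite report --model model/ --features cohort/features.tsv \
    --sample LymphoidLike_s0000 --format text --out report.txt
```

```
Tissue-of-origin report for sample LymphoidLike_s0000
============================================================

Cancer type probabilities (calibrated, gender-filtered):
  LymphoidLike                  1.000 ####################
  BreastLike                    0.000
  CervixLike                    0.000
  ColorectalLike                0.000
  LiverLike                     0.000
  LungSmokingLike               0.000
  ProstateLike                  0.000
  SarcomaLike                   0.000

Top features for LymphoidLike (probability 1.000):
  rmd.LymphoidLike.2    contribution +0.3954  patient 0.724 | LymphoidLike mean 0.5233 | rest mean 0.001305
  sigs.SBS6             contribution +0.3412  patient 0.458 | LymphoidLike mean 0.4623 | rest mean 0.07248
  rmd.LymphoidLike.1    contribution +0.1406  patient 0.2835 | LymphoidLike mean 0.4688 | rest mean 0.001727
  ...
  fusion.IGH            contribution -0.0113  patient absent | LymphoidLike mean 55% | rest mean 0%
```

The probability panel ranks all cancer types; each class panel lists the
features that moved this sample's probability most, with the patient's
value against the class and rest-of-cohort training means. Here the
class-specific RMD profile and the planted signature carry the prediction;
the class's recurrent immunoglobulin heavy-chain fusion (prevalence 55% in
the class, 0% elsewhere) contributes slightly negatively because this
particular patient lacks it — exactly the pattern a reviewer would check
against known biology.

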
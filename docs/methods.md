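# Methods

`primarysite` classifies the tissue of origin (TOO) of a whole-genome
sequenced tumor from its somatic mutation landscape. This note documents the
model, its assumptions, the tunable parameters, the synthetic cohorts the
package is validated on, and the numerical choices made where the design was
genuinely open.

## Feature families

Each sample is summarized into a named feature vector,
`{feature_type}.{feature_name}`:

| family | type | content |
|---|---|---|
| `rmd.*` | numeric | non-negative contributions of regional-mutational-density profiles (see below) |
| `sigs.*` | numeric | mutational-signature exposures, normalized per mutation class |
| `mut_load.*` | numeric | total SBS / DBS / indel counts |
| `gene.*` | boolean | driver events per (gene, event type): amplification, deep deletion, biallelic loss, monoallelic hit |
| `chrom_arm.*` | numeric | arm copy number as fold change vs the modal genome copy number |
| `genome.*` | numeric/boolean | ploidy, diploid proportion, whole-genome-duplication flag |
| `gender.male` | boolean | sample sex (metadata, or inferred from chrX dosage) |
| `sv.*` | numeric | SV-cluster burden: total load, DEL/DUP counts by length, complex clusters by size, LINE insertions, double minutes, breakends of the largest complex cluster |
| `fusion.*`, `viral_ins.*` | boolean | recurrent gene fusions; viral insertions merged into nine virus categories |

**Mutation contexts.** Single-base substitutions are canonicalized to the
pyrimidine strand and classified into the 96 trinucleotide categories;
doublet substitutions into the 78 canonical doublet categories; indels into
the 83-category scheme by length, repeat context and flanking microhomology.
For indels, repeat copies are counted in the 3' direction including the
deleted unit, and microhomology is the longest match between the deleted
sequence and either flank. Context counts are fitted to a signature catalog
by non-negative least squares; child signatures of one process (e.g. the
UV-light family) are summed into their parent, and exposures are divided by
the mutation class's total load so that burden and composition decouple.
The package ships no third-party catalog: `signatures.synthetic_catalog`
builds versioned synthetic catalogs for testing, and any COSMIC-format
contexts-by-signatures table can be supplied at extraction time.

**Regional mutational density (RMD).** The genome is tiled into fixed bins
(1 Mb for real genomes; the bin table is a BED input and must be identical
between training and prediction). A sample's RMD vector is the fraction of
its SBSs in each bin. Because raw bins are high-dimensional and sparse,
training compresses them into cancer-type-specific profiles:

1. *Rank search per class.* For ranks 1–10, KL-divergence NMF runs 50 times
   on a random subset of up to 100 class samples with 10% of matrix entries
   masked out of the loss; masked entries are imputed as (WH) and scored by
   mean squared error. The chosen rank is the one immediately before the
   relative increase of log10(median MSE) first exceeds 0.2%.
2. *Profile extraction.* A full unmasked NMF at the chosen rank yields the
   class's profiles (rows L1-normalized).
3. *Deduplication.* Profiles from all classes are clustered hierarchically
   (complete linkage) on the distance 1 − Pearson correlation and the tree
   is cut at height 0.1; within each group the profile from the class with
   the most training samples is kept (ties by name).
4. *Fitting.* Each sample's RMD vector is regressed on the final profile
   set by non-negative least squares; the coefficients are the `rmd.*`
   features.

The NMF uses multiplicative updates with uniform-random (0, 1] seeded
initialization scaled to the matrix mean, an epsilon of 1e-12 guarding the
divisions, and a relative-loss stopping rule checked every 10 iterations
(cap 2000 iterations). Rank-search fits stop at a relative tolerance of
1e-4 — the default of the NMF implementation the procedure is modeled on —
while the single final factorization per class runs to 1e-8. Masking
semantics: "10% of the values removed" means 10% of matrix entries uniformly
at random; a row that would lose all its entries keeps one.

**Chromosome-arm copy number.** Segments are split at arm boundaries
(acrocentric chromosomes 13/14/15/21/22 expose only a q arm), copy numbers
are rounded half-away-from-zero to integers, and each arm takes the integer
CN covering the largest fraction of the arm (preliminary CN; coverage ties
resolve to the smaller CN). The modal preliminary CN across arms is the
genome CN (ties to the smaller CN). If the winning CN covers less than half
the arm and the genome CN occurs on the arm, the genome CN is assigned
instead; otherwise the preliminary call stands. Arm features are fold
changes vs the genome CN; a genome CN of 0 with a non-zero arm reports a
capped fold change of 10. Whole-genome duplication is flagged at ploidy
> 2.5 (a deliberate simplification of allele-aware callers); sex is taken
from metadata, falling back to chrX dosage (female iff length-weighted mean
chrX CN ≥ 1.5).

**Preliminary screen.** Boolean driver/fusion features are screened before
training: a feature survives if, for at least one class, a one-sided Fisher
exact test gives p < 0.01 with Cramér's V ≥ 0.1; gene features survive at
gene level (all four event types kept if any passes).

## Classifier

One binary random forest per cancer type (one-vs-rest), because informative
features differ radically between types, plus per-class isotonic calibration
so probabilities are comparable across forests.

Per class, in order:

1. **Univariate selection** — numeric features: Wilcoxon rank-sum
   (tie-corrected normal approximation, exact for small tie-free samples)
   with Cliff's delta; boolean features: Fisher exact with Cramér's V.
   Burden/presence families are tested one-sided ("greater in case");
   copy-number families two-sided with the absolute effect thresholded.
   Keep p < 0.01 and effect ≥ 0.1, capped at the 100 best by (effect
   descending, p ascending, name).
2. **Resampling search** — candidate targets are 5 oversampling sizes
   log-spaced from the case-group size up to the geometric mean of the two
   group sizes, crossed with 5 undersampling sizes log-spaced from the
   control-group size down to the same mean. Each pair is scored by mean
   area under the precision-recall curve in stratified 10-fold CV;
   resampling touches training folds only (cases drawn with replacement,
   controls without), never validation folds. Ties go to the
   least-distorting pair.
3. **Forest** — 500 trees, Gini impurity, bootstrap, sqrt(p) candidate
   features per split, grown to purity. Every node stores its positive-class
   fraction; a sample's probability is the mean leaf fraction over trees.
4. **Calibration** — the whole per-class procedure is rerun inside
   stratified 15-fold cross-validation (fold assignment is a deterministic
   hash of seed and sample id dealt round-robin within each class, so runs
   reproduce across platforms); the out-of-fold probabilities train one
   isotonic regression per class (pool-adjacent-violators, linear
   interpolation between knots, clamped outside the observed range).
   RMD profile extraction runs once on the training set before the CV loop;
   the CV rounds rerun selection, resampling search and the forest.
5. **Gender filter** — breast/ovarian/cervix probabilities are zeroed for
   male samples and prostate for female samples (matched on class-name
   prefixes, configurable), applied both before and after calibration so a
   filtered zero cannot be resurrected by the calibrator. Classes with
   fewer than 15 samples are excluded from training.

**Explanations.** Per (class, sample), the forest probability is decomposed
by local increments: walking each tree root-to-leaf, the change in node
positive-fraction at a split is credited to the split feature; averaged
over trees, baseline + Σ contributions reconstructs the raw probability
exactly (residual < 1e-9). The patient report shows the calibrated
probability panel and, for the top class — plus the runner-up classes
whose probability is at least max(0.2, half the top probability), up to
three — the top features by |contribution| with the patient's value, the
class-cohort mean and the rest-cohort mean (frozen at training). The
contribution decomposes the raw forest probability; calibration is a
monotone per-class remap reported alongside, not decomposed.

**Evaluation.** Recall (argmax correct, ties lexicographic), top-2 recall
(true class within the two highest probabilities), precision; micro-averaged
recall equals accuracy. A sample whose probability row is entirely zero
(e.g. gender-filtered everywhere) counts as incorrect for recall and is
excluded from precision denominators; a class never predicted has undefined
precision and is excluded from the micro-average.

## Synthetic cohorts

The generator (`primarysite.simulate`) builds labeled cohorts with the
statistical structure the classifier assumes, at two levels sharing one
record-drawing core so their distributions agree by construction:

- **Feature level** — RMD bins are multinomial draws from each sample's
  planted profile mixture (Dirichlet weights over 2 sparse per-class
  profiles); signature features are produced by actually fitting multinomial
  context draws from the planted spectrum mixture, so they carry realistic
  NNLS noise; boolean markers are Bernoulli at class prevalences; SV
  burdens are Poisson; copy-number and genome features are computed by the
  production encoders from drawn segment records.
- **Raw level** — the same draws are realized as files on a toy genome
  (five contigs, 500 kb total, 10 kb RMD bins — the bin table is a
  parameter throughout, so the code path is identical to a 1 Mb table):
  SBS positions follow the planted profile over bins and their
  trinucleotide contexts follow the planted signature mixture via a per-bin
  trinucleotide index; extraction on these files recovers the planted
  structure (round-trip tested).

The default archetypes (8 classes × 150 samples, ~2000 SBS per sample)
borrow well-known motifs — a male-only prostate-like class with a recurrent
fusion, a female-only HPV-positive cervix-like class, a smoking-signature
lung-like class, an HBV liver-like class, an IGH-fusion lymphoid-like
class, a complex-SV sarcoma-like class — without claiming biological
fidelity. What passing tests show is that the pipeline recovers planted
structure and learns cleanly separable classes; they say nothing about
performance on real tumors, where class overlap, batch effects and
treatment artifacts dominate.

## Desk-scale configuration

`TrainingConfig` defaults mirror the full-scale procedure (500 trees,
5×5 resampling grid with 10-fold CV, 15-fold calibration CV, 50-run NMF
rank search over ranks 1–10). `desk_scale_config()` is the configuration
used by the test suite and worked examples on synthetic cohorts: 100-tree
final forests (25 in the grid search), a 3×3 grid with 3-fold CV, 5-fold
calibration CV, and an 8-run rank search over ranks 1–5 on 60-sample
subsets. These sizes were chosen once as a single-CPU working point for the
synthetic cohorts; on cleanly separable archetypes the reduced search loses
essentially nothing, which would not be true on real data.

## Known limitations

- The exact genomic definition of the reference 1 Mb bin list (gap
  exclusions, included chromosomes) is configurable rather than fixed; bin
  tables must simply be held constant between training and prediction.
- WGD flagging and sex inference are dosage heuristics, not allele-aware.
- The greedy deduplication representative (largest source class) is one of
  several defensible choices; linkage and cut height are configurable.
- Whether grid-search resampling should be refit on the full training set
  (done here) or reuse fold-level resampled sets is ambiguous; refitting is
  the cleaner estimator.
- `sv.DEL`/`sv.DUP` length bins start at 1 kb; shorter clusters are counted
  in the first bin rather than dropped.
- Isotonic calibration can map an entire low range to 0, so a calibrated 0
  is "below the lowest raw probability ever correct", not impossibility.
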
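# Methods

## Problem setting

`cropboost` supports genomic selection (GS) in hybrid breeding programs
organised as a North Carolina-II (NC-II) design: a pool of inbred maternal
lines crossed factorially with a panel of inbred paternal testers. The F1
genotype at every marker is fully determined by its parents (one allele
from each), so genotyping the parents genotypes the whole factorial, and
the practical question is how well marker-based models predict F1
phenotypes — overall, and as a function of how the training set covers the
parents of the candidates being predicted.

## Genotype codings

Two numeric codings of diploid SNP calls are provided.

* **additive012** — copies of the minor allele (0/1/2), with the major
  allele determined from allele frequencies in a reference panel
  (default: all samples; frequency ties broken alphabetically so the
  coding is reproducible across runs). Required by the linear baseline,
  where effects have a per-allele-copy interpretation.
* **tenstate** — a fixed 16-entry map from ordered base pairs to ten
  integer codes (`AA`→0, `AT`/`TA`→1, …, `GG`→9). It uses no population
  statistics, so a sample's code never depends on which other samples are
  in the file.

For a biallelic marker the two codings are strictly monotone recodings of
each other on the three genotype classes. Because the tree learner splits
ordered codes by threshold, any split available under one coding is
available under the other, and retraining under either coding produces
the same trees and predictions (verified bitwise in the tests). This is
the formal content of the "coding schemes are equivalent for tree models"
claim, and it fails for linear models, which is why the ridge baseline
refuses ten-state input.

Missing calls are carried as a reserved sentinel (−1 encoded, NaN at the
model interface).

## Leaf-wise gradient boosting

The booster fits an additive ensemble to first/second-order gradients of
the objective (squared error; logistic; softmax for K classes, K trees
per iteration). Trees grow *leaf-wise*: every current leaf caches its best
candidate split, and the leaf with the globally highest gain is split
next, producing asymmetric trees. Split gain is the canonical
L2-regularised second-order formula

    gain = G_L²/(H_L+λ) + G_R²/(H_R+λ) − (G_L+G_R)²/(H_L+H_R+λ),

leaf weight −G/(H+λ) scaled by the learning rate. Split search is exact:
every distinct observed value of every feature is a candidate threshold
(`x ≤ t` goes left). Internally the search runs on per-feature value bins
with gradient histograms and histogram subtraction (smaller child computed
directly, sibling by subtraction); since codes take at most ten values
plus missing, binning loses nothing.

Numerical choices:

* **Ties.** Equal gains resolve to the lowest feature index, then the
  lowest threshold; equal leaf gains resolve to the oldest leaf. Training
  is deterministic. Exact gain ties between duplicated column partitions
  can differ from a reference enumeration by summation order only; the
  accepted split is always gain-optimal to 1e−9.
* **Missing values** route to the child with more non-missing training
  samples (tie → left). With an order-reversing recoding and a tied
  count this rule is not flip-symmetric; it is irrelevant when no calls
  are missing.
* **Stopping.** A tree stops at `max_leaves` or when no split has gain
  strictly above zero. `min_samples_leaf` (default 20) applies to both
  children, missing included.
* **Defaults** follow common leaf-wise GBM practice: learning rate 0.1,
  100 iterations, 31 leaves, λ = 1. The evaluation studies in the
  acceptance script use a lighter setting (60 iterations, 15 leaves,
  `min_samples_leaf` 10) appropriate to populations of a few hundred
  samples; `grid_search` covers tuning.

**Information gain (IG).** The gain of every accepted split is summed per
marker across all trees; this cumulative objective-derived gain is
reported as the marker's feature importance for every objective
(regression included), alongside split counts.

## Ridge baseline (rrBLUP-style)

`y = μ + Xβ + e` with X the column-centred additive coding and one
shrinkage parameter λ on marker effects: β = (XᵀX+λI)⁻¹Xᵀ(y−ȳ).
`lam="reml"` estimates λ = σ²ₑ/σ²ᵤ of the equivalent random-effect model
by restricted maximum likelihood through the eigendecomposition of the
genomic kernel XXᵀ, maximised by golden-section search on log λ
(tolerance 1e−6). The marker-effect and kernel forms are algebraically
identical; tests check this numerically, and REML recovers a simulated
variance ratio to within a few percent on average at n = 500, 200 markers.

## Phenotypes, GCA, classification labels

Within-group z-scoring (sample SD, n−1) removes systematic mean
differences between tester families; it errors on groups with fewer than
two values or zero variance rather than silently producing non-finite
output. General combining ability of parent *i* is the mean phenotype of
its F1 offspring minus the grand F1 mean; with every F1 contributing to
exactly one parent per side, the offspring-weighted GCAs sum to zero.
Quantile class labels (low / mid / high at the 25% and 75% cuts by
default) are assigned by rank with a stable (value, sample id) ordering,
so tied values get deterministic classes; whether "low trait value" means
"early" or "poor" is the caller's interpretation.

## Evaluation harness

**Parent-coverage frameworks.** `MP` (both parents of every test F1 occur
as parents of training F1s), `M` (mothers covered, test fathers absent
from the training parent set), `P` (symmetric), `neither` (no shared
parents). M/P/neither are built by holding out parent sets and assigning
crosses; MP draws test F1s greedily so every parent keeps at least one
training offspring. Every plan is machine-checkable against its scheme
predicate. The default training:testing ratio is 5:1.

**Sampling scenarios.** Four benchmark designs over the ratio grid 9:1,
7:1, 5:1, 3:1, 1:1, 1:3, 1:5, 1:7, 1:9: fixed test size (train swept),
fixed train size (test swept), and fixed ratios 9:1 and 1:9 with the
population size swept over nine sizes from n to n/9. Fractional sizes are
floored, the counterpart takes the remainder; each grid point yields 30
random plans by default.

**Metrics.** Pearson r between predicted and measured phenotypes
(zero-variance predictions score 0 with a warning); ROC AUC by the
Mann–Whitney rank statistic with midranks on ties; one-vs-rest AUC per
class for three-class tasks. Scalar regressors used as classifiers are
relabelled by the training-set class proportions and scored through
per-class indicators — the relabelling route, not a probability model.

**Marker panels.** Per repeat (default 30): fit on a random 80% of
samples, rank markers by summed IG, retrain on each top-k panel and score
the held-out 20%; a size-matched random panel is scored on the same split
as the control. Panels keep genome column order so results are
order-independent of the ranking.

**Association scan.** Per-marker simple linear regression of the
phenotype on the additive code (two-sided t-test, pairwise-complete
handling of missing calls, monomorphic markers get p = 1). This is a
deliberately simple scan — the toolkit's augmentation demonstration needs
a signal ranking, not a mixed-model GWAS, and kinship correction is out
of scope. `augment_with_predictions` appends model-predicted phenotypes
for unmeasured samples (rows flagged) so the same scan can be run before
and after augmentation.

## The population simulator

`simpop` emulates the data-generating structure the toolkit targets:

* **Maternal pool**: per-chromosome segment mosaics of a small founder
  set (24 by default), fixed to homozygosity. This stands in for a
  multi-founder intercross of inbred lines: it produces founder-derived
  LD blocks at desk scale without simulating generations of
  recombination. Real intercross populations have finer-grained LD decay,
  pedigree relatedness, and selection history that the mosaic does not
  reproduce, so passing tests speak to model mechanics, not to absolute
  precision on real maize data.
* **Testers**: independent homozygous draws from allele frequencies
  shifted by ±`tester_divergence` per marker, creating the
  maternal/paternal stratification visible on a PCA.
* **Crosses**: full factorial (the 207×30 default reproduces a
  6210-hybrid evaluation population; 1428×30 reproduces the full 42,840
  factorial) or a uniform subsample.
* **Phenotypes**: g = Σ aⱼxⱼ + Σ dⱼ1[hetⱼ] + Σ eⱼₖxⱼxₖ over the chosen
  QTL (additive effects standard normal; dominance and epistatic effects
  half-scale), plus Gaussian noise scaled so the *realised* var(g)/var(y)
  equals the requested h² — a deliberate choice that turns heritability
  into an exact test target rather than an expectation.
* **Parent-side variance knobs**: `tester_qtl_frac` fixes a fraction of
  QTL to monomorphic in the testers (shrinking paternal QTL variance);
  `maternal_shift_sd` / `family_shift_sd` add per-mother / per-father
  family effects not carried by any marker, in units of sd(g). The
  framework-ordering study uses large maternal and small paternal family
  effects: such non-marker parental variance is learnable only when the
  parent is covered by training offspring, which is exactly what
  separates the MP/M/P/neither frameworks. Marker count defaults to 500,
  scaled down from the tens of thousands of tag SNPs a real program
  would use.

Identical configs (including seed) give bit-identical populations, and
the stored F1 matrix always equals `geno.infer_f1_genotypes` applied to
its own parents and pedigree.

## Study sizes in the acceptance script

The script simulates its inputs fresh at every run from `--seed`:
coding-equivalence on 600 F1s × 400 markers; 200 random micro-instances
for the split-search oracle; marker panels on an 800-F1, 600-marker,
20-QTL population at h² = 0.5 with 30 subsampling repeats; framework
ordering on a 1200-F1 maternal-dominant population with 20 plans per
scheme; null calibration at n = 300 with 1000 markers; augmentation on
twenty 600-F1 single-QTL replicates at h² = 0.6. These sizes keep every
stage's behaviour measurable with comfortable statistical margins at
desk scale.

## Known limitations

* No imputation or phasing; markers with more than two observed alleles
  are rejected by the additive coding rather than recoded.
* The OLS scan is uncorrected for structure or kinship; its p-values are
  calibrated only under the exchangeable null it is tested against.
* `evaluate_classification` with scalar regressors produces step-function
  ROC curves (relabelling), so their AUCs are coarser than the
  booster's probability-based AUCs.
* The simulator draws environmental noise i.i.d.; no G×E, spatial field
  structure, or multi-environment replication.
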
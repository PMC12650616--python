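# Methods

`tcrdiag` implements a peripheral-blood TCRβ-repertoire diagnostic
pipeline for colorectal cancer (CRC) versus healthy controls (HC):
repertoire summary statistics, clonotype-frequency feature construction,
a ten-family classification benchmark, and cross-validated
permutation-importance biomarker-panel selection, exercised end-to-end on
a synthetic repertoire cohort generator.  This note records the models,
parameter choices, numerical conventions and known limitations.

## Repertoire statistics

A *clonotype* is a unique CDR3 amino-acid sequence; V/J gene variants of
the same CDR3 are kept as separate records but aggregated before any
per-sequence statistic.  With `p_i` the frequency of unique sequence *i*
and *N* the number of unique sequences:

* **Shannon diversity** `H = −Σ p_i log₂ p_i`, in bits, with
  `0·log 0 := 0`.
* **Clonality** `1 − H/log₂(N)`: 0 for a perfectly even repertoire,
  → 1 under extreme oligoclonal expansion.  At `N = 1` the expression is
  0/0 and is **defined as 0**: a single clone has no diversity deficit to
  normalize.  Tiny negative round-off on uniform repertoires is clipped
  to 0.
* **High-expansion clones (HEC)**: unique CDR3s with aggregated frequency
  **strictly above** 0.5% of a sample's reads.  The boundary case
  (exactly 0.5%) does not count; a dedicated test pins this.
* **CDR3 length split**: the frequency-weighted mass at lengths ≤ 14
  (boundary included).
* **V/J usage**: per-gene fractions, read-weighted (summed clone
  frequencies) or clone-weighted (unique clonotype counts).  Gene names
  are normalized by stripping allele suffixes (`*01`) and alignment-score
  annotations; multi-hit fields keep the first (best) hit.

Group comparisons use the two-sided Mann–Whitney U test with midrank tie
handling.  The p-value is exact for small samples — full enumeration of
all group assignments when `n₁+n₂ ≤ 10` (valid under ties), or the
tie-free null-U recursion when `min(n₁,n₂) ≤ 8` without ties — and the
normal approximation with tie and continuity corrections otherwise.
Multiple testing is controlled with the Benjamini–Hochberg step-up
procedure (Benjamini–Yekutieli available), applied jointly within each
feature family (e.g., across all V genes), with the conventional star
tiers on adjusted q-values (\* < 0.05, \*\* < 0.01, \*\*\* < 0.001).
All-constant features are flagged degenerate with p = 1 rather than
tested.

Cross-cohort depth normalization multiplies each sample's clone counts by
`(median total reads of the baseline batch) / (sample total reads)`,
yielding real-valued pseudo-counts.  The median anchor is robust to
depth outliers; the mean is available by option.  Because the scaling is
uniform within a sample, frequency vectors — and hence every statistic
above — are unchanged; only count scales are harmonized.  Batch
adjustment of usage tables (ComBat-seq style) is deliberately out of
scope: externally adjusted tables enter through the same readers.

## Synthetic cohort generator

The generator emulates the statistical structure of a case/control
peripheral-blood TCRβ study so that every downstream stage can be
validated against known ground truth.  Per sample:

1. the unique background clone count is Poisson around the arm mean
   (defaults: HC 2000, CRC 1600 — controls richer);
2. clone probabilities follow a Zipf law `∝ rank^(−a)` (HC a = 1.0,
   CRC a = 1.2 — steeper case spectra give higher clonality and lower
   diversity);
3. CDR3 strings are `C` + random 20-amino-acid junction + `F`, with
   total length from a discrete Gaussian truncated to [8, 24], centered
   at 14.5 for HC and shifted down by `length_shift` (default 1.0) for
   cases — moving case mass toward lengths ≤ 14;
4. V/J segments are drawn from a mildly decreasing base usage profile
   over 20 TRBV / 13 TRBJ functional segments; case V usage is modulated
   by `v_usage_skew` (defaults: TRBV16 and TRBV30 up 1.8×, TRBV6-1 down
   0.5×);
5. *signature clonotypes* — `n_signature = 30` public CDR3s drawn once
   per cohort — are carried by any sample with probability
   `signature_carrier_rate = 0.2`, at frequency
   `signature_base_frequency = 2.5e-4` in controls and
   `signature_enrichment = 10×` that in cases;
6. read counts are one multinomial draw of `total_reads = 20 000` over
   the renormalized probabilities, so spiked clones experience the same
   sampling noise as background clones.

All randomness flows through one seeded generator per cohort with
per-sample substreams keyed by sample index, so cohorts are byte-stable
and order-independent.  External-validation cohorts are generated from a
fresh seed but with the discovery cohort's signature clonotypes passed in
explicitly: fresh individuals of the same disease share the
disease-associated public clonotypes, and without that sharing an
external cohort would have no vocabulary overlap at all (private
background CDR3s essentially never collide).

**Calibration of the signature parameters.**  Sample sizes (100/100),
the signature count (30) and the enrichment (10×) follow the emulated
study design.  Carrier rate and base frequency are free parameters and
were set by two requirements: (i) the signature clonotypes must rank
inside the top-1000 global-frequency vocabulary (public mass across
~40 carriers outranks all but each sample's few top private clones), and
(ii) the default cohort must *not* be perfectly separable — the emulated
study reports an internal-test AUC of 0.973, and a perfectly separable
cohort is both unrealistic and degenerate for permutation importance
(shuffling one of several redundant, individually-sufficient features
leaves validation AUC at 1.0, so every importance ties at zero).  With a
carrier rate of 0.2 the binomial variance of per-sample carrier counts
sets the aggregate case/control separation near 2.5σ, giving
cross-validated AUC ≈ 0.97–0.98 at the defaults.  The calibration used a
seed distinct from any test seed.

What the generator does **not** emulate: V(D)J recombination mechanics
(TdT insertions, trimming), thymic selection, nucleotide-level
convergence, batch effects between sequencing centers, age/sex
covariates, and biological correlation between signature clonotypes and
repertoire-level contrasts (each contrast is injected independently).
Passing tests therefore demonstrate that the *procedures* behave
correctly under known structure, not that real CRC repertoires are
classifiable at any particular accuracy.

## Feature construction

All unique CDR3s across in-scope samples are ranked by **summed relative
frequency** (robust to sequencing depth; presence-count ranking is
available), the top 1000 kept, and the set reduced to 500 by the
two-group ANOVA F statistic; ties in either ranking break
lexicographically on the CDR3 string, and all-constant columns receive
F = 0.  Each sample becomes a vector of aggregated CDR3 frequencies with
absent sequences imputed as zero; labels are encoded 1 = CRC, 0 = HC.

The published recipe selects the vocabulary *globally* — on all samples
before splitting — which leaks test-set information into the feature
definition.  The default scope is therefore `train_only` (split first;
vocabulary and ANOVA filter see only training samples), with
`scope="global"` available to reproduce the published behaviour; both
modes are logged.

The 70/30 split is stratified with per-class test counts from rounding
with largest-remainder reconciliation: 123 cases + 187 controls at 30%
give a 93-sample test set (37/56).

## Classifier benchmark

Ten families: random forest, logistic regression, KNN, decision tree,
Gaussian naive Bayes (no tunables, evaluated at defaults), gradient
boosting, AdaBoost (scikit-learn), and three NumPy neural networks with
hand-written backpropagation and Adam — an MLP, a 1-D CNN reading the
feature vector as a signal over vocabulary rank, and a Transformer
encoder.  In the Transformer each selected clonotype is one token:
token *j* = learned identity embedding(*j*) + the sample's scalar
frequency through a learned value projection; post-norm encoder layers
(self-attention → residual → LayerNorm → feed-forward → residual →
LayerNorm); mean pooling, affine head, sigmoidal link.  `d_model` must
divide by `nhead`; dropout is inverted and training-only; analytic
gradients are verified against central finite differences in the test
suite.

Hyperparameters are selected by exhaustive grid search under stratified
5-fold cross-validation, maximizing mean validation AUC (ties break
toward earlier grid order; a failing grid point scores 0.5 and is
flagged, never dropped).  The winner is refit on the full training
partition and evaluated on the held-out test set.  Desk-scale default
grids carry 1–4 points per family; the full study-style search spaces
ship as `FULL_GRIDS`.

Conventions: CRC is the positive class everywhere; accuracy, recall and
F1 use a 0.5 threshold on the probability scale; AUC uses the
rank/pair-counting formulation with ties counting ½ (verified to equal
the trapezoidal area under the constructed ROC).  Inputs are z-scored on
training statistics for KNN, logistic regression and the neural families;
tree ensembles see raw frequencies.  Per-family seeds are derived from
one master seed by hashing the family name, so adding a family never
perturbs another's randomness.

## Permutation importance and biomarker panels

Within stratified 5-fold cross-validation, each fold fits the model on
its training part, scores the intact validation part, then shuffles each
validation-fold column `n_repeats = 5` times (fresh seeded permutation
per fold × feature × repeat) and records baseline − permuted metric
(AUC by default; accuracy available).  A feature's importance is the
mean over repeats then over retained folds; folds with single-class
validation parts are skipped and the denominator adjusted.
Validation-fold shuffling (rather than whole-dataset shuffling) is the
leakage-safe reading and the standard practice.

The top-k features (default k = 50, ties lexicographic) form the panel;
`retrain_on_panel` restricts the matrices to panel columns and reruns the
full search/refit/evaluate cycle.  On synthetic cohorts the panel is
scored against the generator's ground truth as
`|panel ∩ signatures| / min(|panel|, |signatures|)`.

Any family can drive the importance computation.  The desk-scale
validation runs use the logistic-regression scorer (its per-permutation
scoring cost is negligible, making 10-replicate recovery estimates cheap)
and retrain the Transformer on the resulting panel; the Transformer
scorer is supported but costs ~10⁴ encoder forward passes per run at
m = 500.

## Problem sizes and calibration checks

Validation runs use desk-scale sizes chosen to exercise every code path:
the default 100/100-sample cohort with the full 1000→500 feature recipe
for signal recovery and direction checks; 10 replicate label-permuted
cohorts with a label-independent top-50 vocabulary for null calibration.
The null check deliberately skips ANOVA selection: selecting features on
the training labels and then cross-validating on those same labels
re-uses information and inflates null CV AUC (the published global
recipe carries exactly this leakage), and the calibration probes the
classifiers, not the selection step.  Because a single label permutation
leaves dataset-level chance correlations that all CV folds share,
individual replicate AUCs have heavy tails; the calibration band is
asserted on the replicate-averaged AUC per family.

## Known limitations

* Clone counts are treated as opaque non-negative weights; no
  UMI/read distinction.
* Cohort roles (discovery vs external validation) come from metadata,
  never from accession identity.
* The NumPy networks are CPU-only and desk-scale; no early stopping
  (fixed epoch counts), no probability calibration.
* The CNN's notion of locality is vocabulary-rank adjacency, which is a
  modelling convention, not biology.
* Panel CDR3s are not annotated against external TCR–antigen databases.
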
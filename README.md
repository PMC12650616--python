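# tcrdiag

Peripheral-blood **T-cell receptor (TCR) repertoire diagnostics** for
colorectal cancer (CRC).  The package implements, as a tested and
reusable pipeline, the analysis by which a labelled cohort of TCRβ
clonotype tables (CDR3 amino-acid sequence, TRBV/TRBJ segments, read
count per clone) is turned into a diagnostic classifier and a compact
biomarker panel:

1. **Repertoire statistics** — per-sample unique-clone counts, Shannon
   diversity `H = −Σ pᵢ log₂ pᵢ` (bits), clonality `1 − H/log₂N`,
   high-expansion-clone (HEC, frequency > 0.5%) ratios, CDR3-length
   distributions, and V/J gene usage; CRC-vs-HC comparisons by two-sided
   Mann–Whitney U tests with Benjamini–Hochberg FDR control.
2. **Feature construction** — the top-1000 globally most frequent CDR3s,
   reduced to 500 by ANOVA F-value selection; per-sample frequency
   vectors with zero imputation (`X ∈ ℝ^{n×m}`, y = 1 for CRC);
   stratified 70/30 train/test split.
3. **Classifier benchmark** — ten families (random forest, logistic
   regression, KNN, decision tree, naive Bayes, gradient boosting,
   AdaBoost, MLP, 1-D CNN, and a self-attention Transformer encoder over
   clonotype tokens) tuned by grid search under stratified 5-fold CV
   (selection by mean AUC) and scored on the held-out set with accuracy,
   AUC, recall and F1.
4. **Biomarker panels** — cross-validated permutation importance
   (5 shuffles per feature per validation fold, fold-averaged), top-50
   panel selection, panel retraining, and frozen-model external-cohort
   validation.

Because the original study cohorts are controlled-access sequencing
archives, the package ships a **synthetic cohort generator** that
reproduces the study's statistical structure — power-law clone-size
spectra, case/control contrasts in richness/clonality/HEC ratio, a CDR3
length shift around 14, differential V usage, and spiked public
"signature" clonotypes with known ground truth — so every stage is
validated end-to-end without any data download.  See
[docs/methods.md](docs/methods.md) for the model details and
calibration rationale.

## Worked example

```python
from tcrdiag import (
    SimulationConfig, generate_cohort, cohort_summary_table,
    ModelSpec, fit_final, evaluate,
    permutation_importance_cv, select_panel, panel_recovery_score,
)
from tcrdiag.pipeline import build_features

# a 100-case / 100-control cohort with 30 spiked signature clonotypes
cohort, truth = generate_cohort(SimulationConfig(seed=7))
summary = cohort_summary_table(cohort)
print(summary.groupby("label")[["n_unique", "clonality"]].median())

# top-1000 CDR3s -> ANOVA-500, stratified 70/30 split (leakage-safe scope)
fm_train, fm_test, vocab = build_features(
    cohort, top_k=1000, m_out=500, scope="train_only",
    test_fraction=0.30, seed=7,
)

# logistic-regression benchmark arm
spec = ModelSpec("logistic_regression", seed=7)
model = fit_final(spec, {"C": 1.0}, fm_train)
print("held-out AUC:", round(evaluate(model, fm_test).auc, 3))

# permutation-importance top-50 panel, scored against the ground truth
report = permutation_importance_cv(spec, fm_train, params={"C": 1.0}, seed=7)
panel = select_panel(report, k=50)
print("panel recovery:", panel_recovery_score(panel, truth))
```

Output:

```
       n_unique  clonality
label
CRC      1231.0   0.382190
HC       1790.0   0.255417
```

The CRC arm shows fewer unique clones and higher clonality — the
direction pattern of the emulated study — and then

```
held-out AUC: 1.0
panel recovery: 0.9333333333333333
```

the classifier separates the held-out samples perfectly at this seed,
and 28 of the 30 spiked signature clonotypes appear in the top-50 panel
(recovery counts hits against min(|panel|, |signatures|) = 30).

A command-line interface wraps the same stages:

```bash
tcrdiag simulate --outdir cohort/ --seed 7
tcrdiag stats --cohort-dir cohort/ --outdir out/
tcrdiag run-all --config run.yaml --seed 7
```

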
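# markermeta

Integrative evidence synthesis for expression biomarkers, built around the
multi-cohort case for PLK1 (and its candidate regulator MYCN) in
colorectal cancer.

When a biomarker's evidence is scattered over dozens of heterogeneous
transcriptomic cohorts, several distinct statistical syntheses are
needed to make a coherent case.  `markermeta` implements that toolchain
as one tested package:

* **Random-effects SMD meta-analysis** — per-study Hedges' *g* pooled by
  DerSimonian–Laird, with τ², I², prediction intervals, and Egger/Begg
  publication-bias tests.
* **Diagnostic SROC synthesis** — median dichotomization of expression
  into per-cohort 2×2 tables, Moses–Littenberg summary-ROC regression
  (D = a + bS on logit scale), trapezoidal AUC, and pooled
  sensitivity/specificity via DL on logits.
* **Correlation screening** — per-cohort Pearson correlation between two
  genes with Benjamini–Hochberg FDR control, plus a canonical E-box
  (CANNTG) promoter scan.
* **Expression-derived CNV scoring** — reference centering against a
  diploid population, genomic running-mean smoothing, median filtering,
  mean ± 2 SD thresholding into 0/1/2 scores, and median-split
  malignancy calls for single cells.
* **Spatial autocorrelation** — row-standardized kNN weights, Moran's I,
  bivariate Lee's L, permutation inference, UMI-depth residualization,
  and a composite immune score for spot-level transcriptomics.
* **Seeded synthetic generators** for each stage, with ground truth, so
  every pipeline is testable end-to-end without external data.

The per-cohort diagnostic contingency tables for PLK1 (18 cohorts) and
MYCN (22 cohorts) and the 17-cohort PLK1–MYCN correlation table ship with
the package (`markermeta.datasets`).

## Worked example

```python
from markermeta import datasets, moses_littenberg_fit, pool_logit_accuracy

tables = datasets.load_plk1_contingency()     # 18 cohorts, TP/FP/FN/TN
model = moses_littenberg_fit(tables)          # D = a + b*S, unweighted LS
acc = pool_logit_accuracy(tables)             # DL pooling of logits

print(f"a = {model.a:.3f}, b = {model.b:.3f}, AUC = {model.auc:.4f}")
print(f"sens = {acc.sens:.4f} CI ({acc.sens_ci[0]:.3f}, {acc.sens_ci[1]:.3f})")
print(f"spec = {acc.spec:.4f} CI ({acc.spec_ci[0]:.3f}, {acc.spec_ci[1]:.3f})")
```

prints

```
a = 3.716, b = 0.094, AUC = 0.9293
sens = 0.8376 CI (0.742, 0.902)
spec = 0.8614 CI (0.803, 0.904)
```

i.e. across the 18 cohorts, a median split on PLK1 expression separates
tumor from normal tissue with a summary-ROC area of about 0.93 and pooled
sensitivity/specificity of roughly 0.84/0.86 — an informative, fairly
symmetric diagnostic profile despite the heterogeneity of the underlying
platforms (the near-zero slope *b* indicates little threshold effect).

The same machinery is exposed as a CLI:

```sh
markermeta sroc --tables plk1.csv --out report.json --curve curve.csv
markermeta corr --input correlations.csv --alpha 0.05 --out corr.json
markermeta simulate spatial --seed 1 --out sim/
markermeta spatial --spots sim/spots.csv --fractions sim/fractions.csv \
    --value marker --covariate log_umi --perms 999 --seed 1 --out moran.json
```

Reports are JSON with the full run configuration and input checksums
embedded; logs go to stderr; exit codes are 0 (success), 2 (validation
error), 3 (degenerate model).

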
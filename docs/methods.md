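# Methods

This note documents the statistical models implemented in `markermeta`,
the choices made where conventions genuinely diverge, what the synthetic
generators do and do not emulate, and known limitations.

## Standardized-mean-difference meta-analysis

Per-study effects are Hedges' *g*: the pooled-SD Cohen's *d* multiplied by
the small-sample correction J = 1 − 3/(4m − 1) with m = n₁ + n₀ − 2, with
sampling variance

    var(g) = (n₁ + n₀)/(n₁ n₀) + g² / (2(n₁ + n₀)).

Pooling uses the DerSimonian–Laird (DL) method-of-moments estimator:
τ² = max(0, (Q − df)/C) with C = Σw − Σw²/Σw and fixed-effect weights
w = 1/v; heterogeneity is summarized as I² = max(0, (Q − df)/Q)·100.
Random-effects weights are 1/(v + τ²).

Two interval conventions had to be fixed because the field uses several:

* the **95% CI** on the pooled estimate uses normal quantiles on the
  pooled SE (the classical DL interval);
* the **95% prediction interval** uses a *t* quantile with k − 2 degrees
  of freedom (Higgins convention), hence requires k ≥ 3.

A consequence worth knowing: the DL normal-quantile CI *undercovers* when
between-study variance is large relative to within-study variance.  Our
own simulations at k = 18, μ = 1.75, τ² = 0.63 (the heterogeneity regime
of the bundled multi-platform synthesis) put the true coverage near 92%
rather than 95%, independent of per-study sample size.  This is a
property of the estimator, not of the implementation; methods such as
Hartung–Knapp correct it but are out of scope here.

Publication bias: Egger's regression (g/SE on 1/SE, intercept *t*-test
with k − 2 df) and the Begg–Mazumdar rank test (Kendall's τ-b between
variance-stabilized deviations from the fixed-effect mean and the
sampling variances; two-sided p from the normal approximation to
Kendall's S with tie correction).  The normal approximation is used even
at small k; for k = 3 the exact enumeration p and the approximation rank
candidate orderings identically but differ in level.

## Diagnostic synthesis (SROC)

Each cohort's expression values are dichotomized at the cohort-wide
median; values strictly greater than the median are test-positive (ties
negative), yielding a TP/FP/FN/TN table per cohort.  If any cell of a
table is zero, 0.5 is added to **all four** cells of that table before
any logit.

The Moses–Littenberg model regresses D = logit(sens) − logit(1 − spec)
(the log diagnostic odds ratio) on S = logit(sens) + logit(1 − spec)
(a threshold proxy).  The regression is **unweighted** least squares by
default — the classical variant — with inverse-DOR-variance weighting
available behind a flag.  The summary curve is

    logit(TPR) = a/(1 − b) + ((1 + b)/(1 − b)) · logit(FPR),

valid for |b| < 1 (larger |b| is flagged degenerate).  AUC is trapezoidal
integration on 10,001 evenly spaced FPR grid points with endpoint limits
TPR(0) = 0, TPR(1) = 1; refinement beyond this grid changes the value by
less than 1e-4.

Pooled sensitivity and specificity are **univariate** DL syntheses of the
per-study logits with variances 1/tp + 1/fn and 1/tn + 1/fp on corrected
cells, back-transformed through the inverse logit.  This is an
approximation: it ignores the negative correlation between sensitivity
and specificity that bivariate (Reitsma-type) models capture, and pooled
values can differ by a few percentage points from a bivariate fit of the
same tables.  On the bundled PLK1 tables the univariate pipeline gives
AUC 0.929 and sens/spec 0.838/0.861; on the MYCN tables AUC 0.806 and
sens 0.638.  No single weighting/pooling convention we examined
(unweighted vs inverse-variance regression, zero-cell-only vs blanket
correction, restricted-range AUC, Freeman–Tukey pooling) reproduces the
published summaries of both tables simultaneously; the defaults above are
the documented, internally consistent choice.

## Correlation screening and E-box scan

Pearson r per cohort, with the two-sided p-value from
t = r·sqrt((n − 2)/(1 − r²)) on n − 2 df evaluated through the log-space
survival function, so extreme p-values degrade to the smallest
representable float rather than 0.  BH-FDR adjustment is step-up with m
equal to the number of p-values supplied (for the bundled table, m = 17 —
the published FDR column verifies against that m).  Significance counting
is strict (FDR < α).

The promoter scan matches the canonical E-box hexamer CANNTG on both
strands.  The pattern is its own reverse complement, so every match is
reported twice (strands + and −) at the same plus-strand coordinate.  N
in the sequence matches only the pattern's two degenerate positions.
PWM/log-odds scoring is deliberately out of scope — no weight matrix or
threshold is part of this pipeline.

## Expression-derived CNV scoring

Reference centering (per-gene mean over reference cells subtracted) →
running-mean smoothing over genomically ordered genes within chromosome
(default window 101 genes, truncated at chromosome ends) → sliding median
within chromosome (default width 5) → per-gene thresholding against the
reference's mean ± SD bands **of the smoothed trace** (so thresholds
match the scored quantity): score 0 within 2σ, 1 within (2σ, k·σ], 2
beyond k·σ with k = `k_outer` (default 4; the single-copy/multi-copy
boundary has no canonical value and is a free parameter).  Gains and
losses are scored jointly by absolute deviation; the deviation sign is a
side channel.  Genes with zero reference SD score 0 and are logged.

Per-cell totals are column sums; a cell is called **malignant** when its
total is *strictly* above the median total.  Note the structural
implication: if malignant cells are more than half the population, the
median falls inside the malignant group and the rule's best attainable
accuracy is (n_ref + n_malignant/2)/n — e.g. 0.90 for a 60% clone — no
matter how strong the CNV signal.  The rule presumes a roughly balanced
malignant/normal mix, which is why the recovery tests and the
single-cell generator default to a balanced split.

## Spatial statistics

kNN weights (default k = 6, matching the hexagonal neighborhood of
Visium arrays) are computed by Euclidean distance with self excluded,
distance ties broken by ascending spot index (deterministic), and rows
standardized to sum 1.  The dense distance matrix is computed explicitly —
at Visium scale (thousands of spots) this is cheap, and it is the only
way to guarantee the tie-break contract.

Moran's I uses the standard cross-product form (null expectation
−1/(n−1)); Lee's L combines both variables' spatial lags and is
symmetric in its arguments, with L(x, x) ≥ 0.  Inference is by
permutation: p = (1 + #{T_perm in tail})/(1 + n_perm), default 999
permutations with the one-sided "greater" alternative — the configuration
whose attainable p-values are exactly the floor 0.001 for a maximally
clustered field and 1.000 for an observed statistic in the far opposite
tail.  For bivariate statistics **one** vector (the second argument) is
permuted while the first is held fixed; the reported null expectation is
the permutation mean.  Sequencing-depth artifacts are removed by OLS
residualization of log UMI counts from each variable before re-testing.

The composite immune score is the raw per-spot sum of the CD8+ T, CD4+ T,
B-cell, NK, and macrophage fraction columns.

## Synthetic data: what it emulates, what it does not

* **Cohorts** (`gen_cohorts`): k studies; the biomarker gene's true effect
  δᵢ ~ Normal(μ, τ²) (defaults k = 18, μ = 1.75, τ² = 0.63 — the
  heterogeneity regime of the multi-platform synthesis); tumor values
  Normal(δᵢ, 1), normal values Normal(0, 1); all other genes null; an
  additive per-study batch shift ~ Normal(0, `batch_shift_sd`) on every
  gene.  Per-group sizes are uniform on `n_range` (default 30–100,
  typical of GEO cohorts).
* **Contingency tables** (`gen_contingency`): TP ~ Bin(n₁, sens),
  TN ~ Bin(n₀, spec); defaults sens/spec 0.85/0.86.
* **Single cell** (`gen_single_cell`): Normal(0, 1) log-expression
  baseline; clone cells shifted by the segment amplitude (default one
  50-gene segment at 3σ) on two synthetic chromosomes; default 250
  reference / 250 clone cells (see the malignancy-rule note above).
* **Spatial** (`gen_spatial`): square lattice (default 20×20); expression
  field = moving-average-smoothed Gaussian noise (half-width
  `length_scale`, 0 = white noise) rescaled to unit variance, optionally
  plus a multiple of centered log-UMI (`depth_coupling`) for depth-driven
  artifacts; log UMI has a linear gradient along x; five immune fractions
  from a 6-component softmax of smoothed Gaussian fields (sums < 1).

Not emulated: scRNA-seq dropout and count noise, probe-level microarray
structure, hexagonal spot geometry, realistic deconvolution error, and
correlated gene-gene structure beyond the planted effects.  Passing
recovery tests therefore demonstrate correctness of the *statistics*
under their stated assumptions, not robustness to every artifact of real
omics data.

## Numerical conventions

* Coordinates and genomic positions are 1-based in files, 0-based in
  memory.
* Missing expression values fail fast; no imputation anywhere.
* Batch adjustment fits a two-way additive means model (grand mean +
  group effect + batch effect) per gene by least squares and subtracts
  the mean-centered batch offsets; batches lacking one of the two groups
  pass through unchanged with a warning, as does a single-batch input.
  Naive per-batch centering is avoided because it destroys the
  tumor/normal contrast when group composition differs across batches.
* Degenerate cases: zero threshold spread in the SROC fit fixes b = 0 and
  flags the model; |b| ≥ 1 flags it and blocks the curve back-transform;
  Begg's test with all-equal variances returns p = 1 with a warning;
  constant vectors are rejected by the spatial statistics.
* All simulation seeds are explicit function arguments; permutation
  p-values are bit-reproducible given (seed, n_perm).

## Problem sizes used in the test suite

Recovery and calibration tests run at deliberately modest sizes chosen to
make their statistical targets well-resolved: 500 replicates for CI
coverage, 200 seeds for the Moran null, 999 permutations for p-floor
checks, 500 cells / 200 genes for CNV recovery, and 50 random small
instances per brute-force oracle comparison.

## Known limitations

* Univariate logit pooling of sensitivity/specificity (no bivariate
  model), DL only (no REML/Paule–Mandel/Hartung–Knapp).
* The SROC AUC integrates the full FPR range, including regions far from
  the observed operating points.
* CNV scores are burden scores, not integer copy numbers; no HMM
  segmentation or subclone inference.
* Spatial inference is global (no local indicators); weights are kNN only.
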
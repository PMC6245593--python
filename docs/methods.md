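# Methods

## Model

BLASSO is a binary linear classifier with a heterogeneous L1 penalty. For
samples `(x_i, y_i)`, `y_i in {0, 1}`, it minimizes

```
(1/n) sum_i log(1 + exp(-(2 y_i - 1)(b0 + x_i . beta)))
    + lambda * sum_j gamma_j |beta_j|
```

over the coefficients `beta` and the unpenalized intercept `b0`. The loss is
the mean logistic negative log-likelihood: it is convex, its optimum
coincides with penalized maximum likelihood, and it admits exact
subgradient (KKT) optimality certificates. With `gamma_j = 1` for all j the
model is the standard L1-penalized logistic LASSO; with `gamma_j = 0` it is
plain logistic regression. (A squared-error-of-sigmoid composition is
sometimes written for this family of models; it is non-convex and is
deliberately not implemented — the glmnet-style binomial likelihood is what
such analyses actually fit.)

The penalty factors encode literature-derived prior relevance:

```
gamma_j = (1 / (#cites_j + 1)) ** epsilon,    epsilon in (0, 1]
```

`#cites_j` counts *distinct* citing articles (a gene mentioned five times in
one article counts once), either across all literature (gene-specific mode)
or joined by article ID against a disease-term list (gene-disease mode;
exact string match after case-folding, no ontology expansion). Genes absent
from the citation table have zero citations, hence `gamma = 1`. Exact zeros
(`gamma_j = 0`, fully unpenalized genes) cannot arise from finite counts and
are only available through an explicit override, as required by the
ideal-prior synthetic setting.

## Optimizer

Cyclic coordinate descent on a majorization of the loss. The logistic loss
has curvature at most 1/4 in the linear predictor, so the quadratic
expansion with constant weight 1/4 is a *global* majorizer; every
coordinate-descent sweep on it decreases the true penalized objective, which
makes the recorded objective trace provably non-increasing. Details:

- Features are standardized internally (mean 0, population variance 1);
  coefficients are returned on the original scale. `standardize=False`
  retains raw scales (columns are still centered against the intercept), as
  needed for the rescaling identity `weighted-lasso(X, gamma) =
  plain-lasso(X / gamma)` to hold exactly.
- Sweeps alternate between the full feature set and the active set (nonzero
  or unpenalized features). Convergence is declared when a full sweep moves
  no coefficient by more than `tol` (default 1e-7) **or** the KKT violation
  drops below `kkt_tol` (default `tol / 10`). The second criterion matters
  near flat optima: where fitted probabilities approach 0 or 1 the 1/4
  majorizer overestimates curvature and coefficient steps shrink very
  slowly even though the iterate is already optimal to high accuracy.
  Non-convergence within `max_sweeps` (default 1e5) raises a warning with
  the final KKT violation.
- `lambda_max`, the top of the regularization path, is
  `max_j |x_j . (y - ybar)| / (n gamma_j)` over penalized features when all
  `gamma_j > 0`. When unpenalized features are present they sit in the model
  at every `lambda`, so the score is evaluated at their restricted maximum
  likelihood fit instead of at the null model. A relative nudge (1e-10, or
  1e-6 above the profiled fit's tolerance) resolves the boundary KKT tie to
  exactly zero coefficients.
- Paths use a geometric grid of 100 lambdas down to `lambda_max * ratio`
  (ratio 0.01 when p > n, 1e-4 otherwise, following glmnet's convention),
  warm-starting each fit from the previous one.
- Degenerate inputs: single-class labels raise a dedicated error;
  `lambda = 0` is allowed only when every feature is unpenalized; constant
  columns keep coefficient zero.

## Validation protocol

R repetitions of stratified K-fold cross-validation (study design: R = 100,
K = 10). Stratification is on by default: with a 199/1013 class imbalance,
unstratified folds risk single-class inner splits; it can be switched off.
Repetition r draws its folds from sub-seed `seed + r`, so plans are
reproducible and distinct across repetitions; two models evaluated with the
same seed share identical folds and can be compared pairwise.

Within each training split, hyper-parameters are tuned by an inner CV
(default 5-fold): for every `epsilon` in the grid the penalty vector is
rebuilt, a lambda path is scored by mean validation AUC, and the best
`(epsilon, lambda)` pair is refit on the whole training split. Ties break
toward larger `epsilon`, then larger `lambda` (more regularization). The
inner selection criterion is AUC to match the reporting metric (the
deviance would be the other natural choice); lambda is chosen at the inner
optimum, not by a one-standard-error rule. The default epsilon grid
`{0.01, 0.05, 0.1, 0.11, 0.15, 0.2, 0.3, ..., 1.0}` covers (0, 1] with
extra resolution at the small end. Inner tuning fits run at a looser
tolerance (1e-5, capped sweeps) than direct fits; they only need to rank
validation samples stably. The inner split is anchored to sample identity
(rows are sorted by sample ID before splitting) so the whole report is
invariant to a permutation of the input rows.

Metrics:

- **AUC** uses the rank (Mann–Whitney) formulation — the probability that a
  random case outranks a random control, ties counted 1/2.
- **Robustness index**: per repetition,
  `RI^(rep) = |intersection of the K fold signatures| / mean signature
  size` (0 when all signatures are empty); aggregated as mean ± SD over
  repetitions. It lies in [0, 1] since the intersection can be no larger
  than the smallest signature.
- **Model comparison**: two-sided Wilcoxon signed-rank on the R*K paired
  fold AUCs (pairing on repetition means is available as an option; the
  fold-level pairing is the default). Zero differences are dropped; if all
  differences are zero the comparison is reported as degenerate with p = 1.
- The 95% interval on AUC is the 2.5/97.5 percentile range of
  repetition-mean AUCs. CV repetitions are not independent, so the interval
  has no exact coverage guarantee and is labelled descriptive in the output.

## Synthetic data

The generator emulates a log2-scale RNA-Seq matrix without shipping any
cohort: Gaussian variables in equicorrelated blocks (default block size 50,
within-block correlation 0.4) mimicking co-expression modules, scaled to
`6 + 2z` and truncated at zero. It does **not** reproduce the mean–variance
relation of count data, between-block correlation structure, library-size
effects, or heavy-tailed expression outliers — so passing tests demonstrate
correct behavior of the selection machinery under correlated designs, not
performance on real cohorts.

The planted outcome draws k causal genes uniformly, coefficients
`beta ~ Unif[0, 1]`, and labels by thresholding the sigmoid of the linear
score at 1/2 (the boundary maps to class 1). Because raw log2 expression
and the coefficients are both non-negative, the raw score is almost surely
positive and would yield a single class; the causal columns are therefore
mean-centered before thresholding. This centering is this package's
interpretation, chosen as the minimal change that makes both classes occur
at realistic balance. Label noise flips exactly `round(flip * n)` uniformly
chosen labels; the flip fraction defaults to 0.05 (the original experiment
reports flipping "some" labels without a rate) and is recorded in the truth
object together with seeds, coefficients and flip indices.

The planted-truth experiment evaluates six named settings: plain LASSO on
the causal genes plus 100 or 1900 random decoys, on all genes, and on all
genes minus the causal ones; and two informed-prior settings on all genes —
E1 (`gamma = alpha ~ Unif(0, 1)` on causal genes) and E2 (`gamma = 0`,
fully unpenalized causal genes), both at `epsilon = 1`. Decoy sampling and
the E1 alpha draw use fixed sub-seeds. Per setting and fold, lambda is
tuned by inner CV and the held-out fold yields test AUC, signature size
(#genes) and overlap with the planted set (#genes*). E2 recovers all k
causal genes by construction of the penalty — that the pipeline reports
exactly k is an end-to-end check of the solver's treatment of unpenalized
features.

## Problem sizes used by the test suite

Full-scale runs of the repeated-CV protocol (100 x 10-fold on 20k genes) are
multi-hour jobs; the suite validates the same code paths at sizes chosen to
keep the complete run in minutes while leaving the tested properties
clearly resolved: the ideal-prior (E2) recovery runs at n = 1212, p = 2000,
k = 100 with 10-fold CV; the decoy-dilution orderings at n = 400, p = 1000,
k = 10 over five seeds; solver-oracle equivalences at n = 50 with 5–25
features, where independent solvers (Newton maximum likelihood, saga-based
L1 logistic regression) converge to high precision.

## Known limitations

- The exact AUC decimals of the original planted-truth table depend on the
  real cohort's expression matrix and an unstated flip rate; only the
  orderings and the exact E2 recovery are reproducible, and that is what is
  asserted.
- The squared-sigmoid objective variant is not implemented (non-convex; see
  Model above).
- Citation counting consumes static association extracts; no online lookup,
  no gene-identifier conversion, no ontology-aware disease matching.
- A cross-*repetition* stability statistic (as opposed to the
  within-repetition robustness index) is not defined in this package.
- Single-lambda fits at strong separation (tiny lambda, unpenalized
  features) rely on the KKT stopping criterion; coefficient estimates there
  are accurate but may differ from another solver's in the last digits.
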
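# blasso

Weighted-L1 logistic regression for gene-expression outcome prediction, with
penalty factors derived from the biomedical literature.

## The problem

A *genetic signature* is the small set of genes a sparse classifier retains
when predicting a clinical outcome (say, vital status) from an RNA-Seq
expression matrix. The standard tool is the LASSO: logistic regression with
an L1 penalty that drives most coefficients to exactly zero. But with tens of
thousands of strongly correlated genes and a few hundred samples, the
selected signature is notoriously unstable — re-run the cross-validation and
a largely different gene set comes back.

`blasso` implements **BLASSO** (Biological LASSO), which stabilizes and
sharpens selection by penalizing each gene according to how much prior
evidence the literature holds for it. For gene *j* with `#cites_j` citing
articles, the model minimizes

```
min_{b0, beta}  (1/n) * sum_i log(1 + exp(-(2 y_i - 1)(b0 + x_i . beta)))
                + lambda * sum_j gamma_j |beta_j|,

gamma_j = (1 / (#cites_j + 1)) ** epsilon,      epsilon in (0, 1]
```

An uncited gene keeps the full penalty (`gamma = 1`); a heavily cited gene is
nearly unpenalized and survives regularization whenever it carries signal.
The exponent `epsilon` flattens the prior (`epsilon -> 0` recovers the plain
LASSO in the limit); both `lambda` and `epsilon` are tuned by nested
cross-validation, never on the held-out fold.

Citation counts come in two modes: **gene-specific** (all articles mentioning
the gene) and **gene-disease** (only articles that also mention a disease of
interest), built offline from static article–gene and article–disease
association tables (PubTator-style extracts).

The package also ships the full validation protocol from the study design it
follows — repeated stratified 10-fold CV with nested hyper-parameter tuning,
AUC scoring, a robustness index `RI = |intersection of fold signatures| /
mean signature size` averaged over repetitions, and paired Wilcoxon
signed-rank model comparison — plus a synthetic-data module that plants a
known causal gene set and measures how well each model recovers it.

## Worked example

```python
import numpy as np
from blasso import (Blasso, CitationTable, build_penalty_vector,
                    make_synthetic_dataset, make_cv_plan, evaluate_model,
                    compare_models, PenaltyVector)

# a planted-truth dataset: 8 causal genes among 150, 5% label noise
ds, truth = make_synthetic_dataset(n=300, p=150, k=8, block_size=25,
                                   within_block_corr=0.4, flip_fraction=0.05,
                                   seed=7)
# pretend the causal genes are well studied: 500 citing articles each
table = CitationTable(counts={g: 500 for g in truth.causal_genes})
penalty = build_penalty_vector(ds, table, epsilon=0.5)

model = Blasso.from_dataset(ds, penalty)
res = model.fit(lam=0.5 * model.lambda_max())
print(res.summary(max_rows=8))
```

```
BLASSO (weighted-L1 logistic regression)
========================================================
No. observations:        300    lambda:    2.93608
No. features:            150    epsilon:   0.5
Selected genes:            3    converged: True
Intercept:           -2.2317    KKT viol.: 7.80e-10
--------------------------------------------------------
gene                          beta       gamma
G00144                     0.25133      0.0447
G00034                     0.09747      0.0447
G00147                     0.04415      0.0447
========================================================
```

At this heavy regularization (half of `lambda_max`, the rate that zeroes
every penalized coefficient) only three genes survive — all of them planted
causal genes, kept alive by their small penalty factors (`gamma = 0.045`
instead of 1). The full protocol compares BLASSO against the homogeneous
LASSO baseline on identical folds:

```python
plan = make_cv_plan(ds.n_samples, K=5, R=3, seed=7, stratify_labels=ds.labels)
blasso_rep = evaluate_model(ds, lambda e: build_penalty_vector(ds, table, e),
                            plan, epsilon_grid=[0.1, 0.5, 1.0], inner_K=3,
                            n_lambdas=30, model_name="BLASSO")
lasso_rep = evaluate_model(ds, lambda e: PenaltyVector.ones(ds.n_genes),
                           plan, epsilon_grid=[1.0], inner_K=3,
                           n_lambdas=30, model_name="LASSO")
print(blasso_rep.summary())
print(lasso_rep.summary())
print(compare_models(blasso_rep, lasso_rep))
```

```
BLASSO: AUC 0.9532 [0.9498, 0.9553] (percentile CI over repetitions; descriptive only), #genes 9.67, RI 0.7673+/-0.1319 (3x5-fold CV, seed 7)
LASSO: AUC 0.9346 [0.9261, 0.9466] (percentile CI over repetitions; descriptive only), #genes 18.53, RI 0.4510+/-0.1186 (3x5-fold CV, seed 7)
Wilcoxon signed-rank on 15/15 nonzero pairs: W = 5.5, p = 0.00196, mean AUC difference = +0.0186
```

The informed prior wins on every axis: higher AUC (+0.019, p = 0.002 on
paired folds), half the signature size, and a markedly more stable signature
(robustness index 0.77 vs 0.45 — on average 77% vs 45% of the mean signature
is common to all five folds of a repetition).

The same workflows are available from the shell:

```bash
blasso priors   --gene-assoc gene2pubtator.tsv --out run/priors
blasso evaluate --expression expr.tsv --counts run/priors_counts.tsv \
                --out run/blasso -K 10 -R 100 --seed 0
blasso evaluate --expression expr.tsv --out run/lasso -K 10 -R 100 --seed 0
blasso compare  run/blasso run/lasso
blasso synth    --out run/table2          # planted-truth experiment
```

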
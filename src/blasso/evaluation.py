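"""Validation protocol: repeated K-fold CV, AUC, robustness index.

Model performance is assessed with R repetitions of stratified K-fold
cross-validation.  Within every training split a second, inner CV selects the
hyper-parameters (lambda, epsilon) by mean validation AUC, so the held-out
fold never informs tuning.  Signature stability is summarized by the
robustness index

    RI = mean_r RI^(r),
    RI^(r) = |intersection of the K fold signatures| / mean fold signature size,

which is 1 when every fold of a repetition selects the same genes and 0 when
no gene is common to all folds.  Paired model comparison uses the two-sided
Wilcoxon signed-rank test on per-fold AUC differences.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from .data_io import ExpressionDataset
from .model import Blasso, BlassoResults, ConvergenceWarning
from .priors import PenaltyVector

__all__ = [
    "CVError",
    "CVPlan",
    "make_cv_plan",
    "auc",
    "robustness_index_rep",
    "robustness_index",
    "NestedCVResult",
    "nested_cv_fit",
    "EvaluationReport",
    "evaluate_model",
    "ComparisonResult",
    "compare_models",
    "DEFAULT_EPSILON_GRID",
]

logger = logging.getLogger(__name__)

# Covers (0, 1] with extra resolution near the small-epsilon end; configurable.
DEFAULT_EPSILON_GRID = (
    0.01, 0.05, 0.1, 0.11, 0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
)


class CVError(ValueError):
    """Raised for invalid cross-validation configuration."""


@dataclass
class CVPlan:
    """Fold assignments for R repetitions of K-fold cross-validation."""

    K: int
    R: int
    seed: int
    assignments: np.ndarray  # shape (R, n); fold id of each sample
    stratified: bool = True

    @property
    def n(self) -> int:
        return self.assignments.shape[1]

    def folds(self, rep: int):
        """Yield (train_idx, test_idx) for each fold of repetition ``rep``."""
        a = self.assignments[rep]
        for k in range(self.K):
            yield np.flatnonzero(a != k), np.flatnonzero(a == k)

    def same_plan(self, other: "CVPlan") -> bool:
        return (
            self.K == other.K
            and self.R == other.R
            and np.array_equal(self.assignments, other.assignments)
        )


def make_cv_plan(
    n: int,
    K: int,
    R: int,
    seed: int,
    stratify_labels: np.ndarray | None = None,
) -> CVPlan:
    """Build fold assignments; repetition r uses sub-seed ``seed + r``.

    Folds partition the samples with sizes differing by at most one, and are
    stratified by label when ``stratify_labels`` is given.
    """
    if K < 2:
        raise CVError("K must be at least 2")
    if K > n:
        raise CVError(f"cannot split {n} samples into {K} folds")
    if stratify_labels is not None:
        smallest = int(np.bincount(np.asarray(stratify_labels)).min())
        if smallest < K:
            raise CVError(
                f"stratified {K}-fold split impossible: smallest class has "
                f"{smallest} samples"
            )
    assignments = np.empty((R, n), dtype=np.int32)
    for r in range(R):
        if stratify_labels is not None:
            splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed + r)
            args = (np.zeros(n), stratify_labels)
        else:
            splitter = KFold(n_splits=K, shuffle=True, random_state=seed + r)
            args = (np.zeros(n),)
        try:
            for k, (_, test_idx) in enumerate(splitter.split(*args)):
                assignments[r, test_idx] = k
        except ValueError as exc:  # e.g. a class smaller than K
            raise CVError(f"stratified {K}-fold split impossible: {exc}") from exc
    return CVPlan(K=K, R=R, seed=seed, assignments=assignments,
                  stratified=stratify_labels is not None)


def auc(scores, labels) -> float:
    """Area under the ROC curve, rank (Mann-Whitney) formulation.

    The probability that a uniformly chosen case outranks a uniformly chosen
    control, with ties counted 1/2.  Both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise CVError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


def robustness_index_rep(signatures: Sequence[frozenset | set]) -> float:
    """Overlap of the K fold signatures relative to their mean size.

    ``|intersection| / mean(|signature_k|)``; defined as 0 when every
    signature is empty.
    """
    if len(signatures) < 2:
        raise CVError("need at least 2 fold signatures")
    sizes = [len(s) for s in signatures]
    mean_size = float(np.mean(sizes))
    if mean_size == 0:
        return 0.0
    inter = frozenset.intersection(*[frozenset(s) for s in signatures])
    return len(inter) / mean_size


def robustness_index(per_rep: Sequence[float]) -> tuple[float, float]:
    """Mean and standard deviation of per-repetition robustness indices."""
    if len(per_rep) == 0:
        raise CVError("no per-repetition values")
    arr = np.asarray(per_rep, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


@dataclass
class NestedCVResult:
    """Hyper-parameters chosen by inner CV and the refitted model."""

    epsilon: float
    lam: float
    results: BlassoResults
    inner_score: float
    # mean inner validation AUC per (epsilon, lambda); keyed by epsilon
    score_curves: dict[float, np.ndarray] = field(default_factory=dict)
    lambda_grids: dict[float, np.ndarray] = field(default_factory=dict)


def nested_cv_fit(
    ds: ExpressionDataset,
    gamma_builder: Callable[[float], PenaltyVector],
    epsilon_grid: Sequence[float] = DEFAULT_EPSILON_GRID,
    inner_K: int = 5,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float | None = None,
    tol: float = 1e-5,
    stratify: bool = True,
) -> NestedCVResult:
    """Select (epsilon, lambda) by inner CV on ``ds`` and refit on all of it.

    For each epsilon in the grid, the penalty vector is rebuilt and a
    lambda path is scored by mean validation AUC over ``inner_K`` folds; the
    (epsilon, lambda) pair with the best mean AUC wins.  Ties break toward
    larger epsilon, then larger lambda (more regularization).  Degenerate
    inner folds (single-class validation split) are skipped with a warning.
    """
    if not epsilon_grid:
        raise CVError("epsilon grid is empty")
    if any(not 0.0 < e <= 1.0 for e in epsilon_grid):
        raise CVError("epsilon grid must lie in (0, 1]")
    # anchor the inner split to sample identity, not row position, so the
    # whole protocol is invariant to a permutation of the input rows
    ds = ds.subset_samples(np.argsort(np.asarray(ds.sample_ids)))
    y = ds.labels
    inner_plan = make_cv_plan(
        ds.n_samples, inner_K, 1, seed, stratify_labels=y if stratify else None
    )
    folds = list(inner_plan.folds(0))
    best: tuple[float, float, float] | None = None  # (score, eps, lam)
    curves: dict[float, np.ndarray] = {}
    grids: dict[float, np.ndarray] = {}
    best_gamma = None
    for eps in epsilon_grid:
        gamma = gamma_builder(eps)
        full_model = Blasso.from_dataset(ds, gamma)
        lambdas = full_model.lambda_grid(n_lambdas, lambda_min_ratio)
        fold_scores = []
        for train_idx, val_idx in folds:
            if y[val_idx].min() == y[val_idx].max() or y[train_idx].min() == y[train_idx].max():
                warnings.warn("skipping degenerate inner fold (single class)")
                continue
            sub_model = Blasso.from_dataset(ds.subset_samples(train_idx), gamma)
            inner_lams = lambdas[lambdas <= sub_model.lambda_max()]
            # lambdas above the inner-train lambda_max give the null model,
            # whose constant prediction scores AUC 1/2 under the tie rule
            scores = np.full(len(lambdas), 0.5)
            if len(inner_lams):
                # tuning fits are capped and not warned about: near-separable
                # splits at tiny lambda converge slowly yet rank validation
                # samples identically for AUC purposes
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    path = sub_model.fit_path(lambdas=inner_lams, tol=tol,
                                              max_sweeps=10_000)
                probs = path.predict(ds.matrix[val_idx])
                off = len(lambdas) - len(inner_lams)
                for i in range(len(inner_lams)):
                    scores[off + i] = auc(probs[i], y[val_idx])
            fold_scores.append(scores)
        if not fold_scores:
            raise CVError("every inner fold was degenerate")
        mean_scores = np.nanmean(np.vstack(fold_scores), axis=0)
        curves[eps] = mean_scores
        grids[eps] = lambdas
        i_best = int(np.argmax(mean_scores))  # first max -> largest lambda
        cand = (float(mean_scores[i_best]), float(eps), float(lambdas[i_best]))
        if best is None or cand[0] >= best[0]:
            # >= so that score ties resolve to the larger epsilon
            best = cand
            best_gamma = gamma
    score, eps, lam = best
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        refit = Blasso.from_dataset(ds, best_gamma).fit(lam, tol=tol,
                                                        max_sweeps=20_000)
    return NestedCVResult(
        epsilon=eps, lam=lam, results=refit, inner_score=score,
        score_curves=curves, lambda_grids=grids,
    )


@dataclass
class EvaluationReport:
    """Per-fold AUCs, signatures and stability aggregates for one model."""

    plan: CVPlan
    auc_values: np.ndarray  # shape (R, K)
    signatures: list[list[frozenset]]  # [rep][fold]
    chosen_hparams: list[list[tuple[float, float]]]  # [rep][fold] -> (eps, lam)
    model_name: str = "BLASSO"

    @property
    def ri_per_rep(self) -> np.ndarray:
        return np.array([robustness_index_rep(sigs) for sigs in self.signatures])

    @property
    def ri(self) -> float:
        return robustness_index(self.ri_per_rep)[0]

    @property
    def ri_sd(self) -> float:
        return robustness_index(self.ri_per_rep)[1]

    @property
    def mean_auc(self) -> float:
        return float(self.auc_values.mean())

    @property
    def n_genes(self) -> float:
        """Average signature size over all (repetition, fold) models."""
        return float(np.mean([len(s) for sigs in self.signatures for s in sigs]))

    def auc_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Percentile interval of repetition-mean AUCs.

        Cross-validation repetitions are not independent, so this interval
        has no exact coverage guarantee and should be read descriptively.
        """
        rep_means = self.auc_values.mean(axis=1)
        lo = (1.0 - level) / 2.0 * 100.0
        return tuple(np.percentile(rep_means, [lo, 100.0 - lo]))

    def summary(self) -> str:
        ci = self.auc_ci()
        return (
            f"{self.model_name}: AUC {self.mean_auc:.4f} "
            f"[{ci[0]:.4f}, {ci[1]:.4f}] (percentile CI over repetitions; "
            f"descriptive only), #genes {self.n_genes:.2f}, "
            f"RI {self.ri:.4f}+/-{self.ri_sd:.4f} "
            f"({self.plan.R}x{self.plan.K}-fold CV, seed {self.plan.seed})"
        )

    def auc_frame(self) -> pd.DataFrame:
        R, K = self.auc_values.shape
        rows = [
            {
                "repetition": r,
                "fold": k,
                "auc": self.auc_values[r, k],
                "epsilon": self.chosen_hparams[r][k][0],
                "lambda": self.chosen_hparams[r][k][1],
                "n_genes": len(self.signatures[r][k]),
            }
            for r in range(R)
            for k in range(K)
        ]
        return pd.DataFrame(rows)

    def signature_frame(self) -> pd.DataFrame:
        """Gene x (repetition, fold) membership matrix (0/1)."""
        genes = sorted(set().union(*[s for sigs in self.signatures for s in sigs]))
        cols = {}
        for r, sigs in enumerate(self.signatures):
            for k, s in enumerate(sigs):
                cols[f"r{r}_f{k}"] = [int(g in s) for g in genes]
        return pd.DataFrame(cols, index=pd.Index(genes, name="gene_symbol"))

    def save(self, prefix: str) -> None:
        """Write ``<prefix>.json`` aggregates plus per-fold TSV tables."""
        self.auc_frame().to_csv(f"{prefix}_auc.tsv", sep="\t", index=False)
        self.signature_frame().to_csv(f"{prefix}_signatures.tsv", sep="\t")
        agg = {
            "model": self.model_name,
            "seed": int(self.plan.seed),
            "K": int(self.plan.K),
            "R": int(self.plan.R),
            "mean_auc": self.mean_auc,
            "auc_ci95": list(self.auc_ci()),
            "ri": self.ri,
            "ri_sd": self.ri_sd,
            "n_genes": self.n_genes,
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(agg, fh, indent=1)


def evaluate_model(
    ds: ExpressionDataset,
    gamma_builder: Callable[[float], PenaltyVector],
    plan: CVPlan,
    epsilon_grid: Sequence[float] = DEFAULT_EPSILON_GRID,
    inner_K: int = 5,
    n_lambdas: int = 100,
    lambda_min_ratio: float | None = None,
    tol: float = 1e-5,
    model_name: str = "BLASSO",
) -> EvaluationReport:
    """Run the full nested-CV protocol and collect an EvaluationReport.

    For every (repetition, fold) of ``plan``: hyper-parameters are tuned by
    inner CV on the K-1 training folds, the tuned model is refit on the
    training split, and AUC plus the selected-gene signature are recorded on
    the held-out fold.
    """
    if plan.n != ds.n_samples:
        raise CVError("CV plan does not cover this dataset")
    R, K = plan.R, plan.K
    auc_values = np.empty((R, K))
    signatures: list[list[frozenset]] = []
    chosen: list[list[tuple[float, float]]] = []
    for r in range(R):
        sig_r: list[frozenset] = []
        par_r: list[tuple[float, float]] = []
        for k, (train_idx, test_idx) in enumerate(plan.folds(r)):
            train = ds.subset_samples(train_idx)
            sel = nested_cv_fit(
                train,
                gamma_builder,
                epsilon_grid=epsilon_grid,
                inner_K=inner_K,
                seed=plan.seed + 1009 * r + k,
                n_lambdas=n_lambdas,
                lambda_min_ratio=lambda_min_ratio,
                tol=tol,
                stratify=plan.stratified,
            )
            probs = sel.results.predict(ds.matrix[test_idx])
            auc_values[r, k] = auc(probs, ds.labels[test_idx])
            sig_r.append(sel.results.signature)
            par_r.append((sel.epsilon, sel.lam))
        signatures.append(sig_r)
        chosen.append(par_r)
        logger.info(
            "repetition %d/%d: mean AUC %.4f", r + 1, R, auc_values[r].mean()
        )
    return EvaluationReport(
        plan=plan,
        auc_values=auc_values,
        signatures=signatures,
        chosen_hparams=chosen,
        model_name=model_name,
    )


@dataclass
class ComparisonResult:
    """Two-sided Wilcoxon signed-rank comparison of paired fold AUCs."""

    statistic: float
    pvalue: float
    n_pairs: int
    n_nonzero: int
    mean_difference: float
    degenerate: bool = False  # every paired difference was zero

    def __str__(self) -> str:
        if self.degenerate:
            return "identical paired AUCs: test degenerate, p = 1"
        return (
            f"Wilcoxon signed-rank on {self.n_nonzero}/{self.n_pairs} nonzero "
            f"pairs: W = {self.statistic:g}, p = {self.pvalue:.3g}, "
            f"mean AUC difference = {self.mean_difference:+.4f}"
        )


def compare_models(
    report_a: EvaluationReport,
    report_b: EvaluationReport,
    unit: str = "folds",
) -> ComparisonResult:
    """Paired Wilcoxon signed-rank test between two evaluation runs.

    Both reports must come from the same CVPlan so that fold AUCs pair up.
    ``unit`` pairs either individual folds (R*K pairs, default) or
    repetition means (R pairs).  Zero differences are dropped, as in the
    standard procedure; if all differences are zero the test is undefined
    and reported as p = 1 with ``degenerate=True``.
    """
    if not report_a.plan.same_plan(report_b.plan):
        raise CVError("reports use different CV plans; folds cannot be paired")
    if unit == "folds":
        a = report_a.auc_values.ravel()
        b = report_b.auc_values.ravel()
    elif unit == "repetitions":
        a = report_a.auc_values.mean(axis=1)
        b = report_b.auc_values.mean(axis=1)
    else:
        raise CVError(f"unknown pairing unit {unit!r}")
    diff = a - b
    nz = diff[diff != 0]
    if len(nz) == 0:
        return ComparisonResult(0.0, 1.0, len(diff), 0, 0.0, degenerate=True)
    stat, p = stats.wilcoxon(nz, alternative="two-sided")
    return ComparisonResult(
        statistic=float(stat),
        pvalue=float(p),
        n_pairs=len(diff),
        n_nonzero=len(nz),
        mean_difference=float(diff.mean()),
    )
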
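"""Synthetic expression data with a planted sigmoid outcome.

The generator emulates a log2-scale RNA-Seq matrix: Gaussian values with
block-equicorrelated columns (co-expression modules), shifted/scaled to a
typical log2 range and truncated at zero.  A known outcome is planted by
drawing k causal genes and coefficients beta ~ Unif[0, 1] and thresholding
the sigmoid of the linear score,

    y_i = 1  if  1 / (1 + exp(-x_i . beta)) >= 0.5   (i.e. x_i . beta >= 0),

then flipping a fixed fraction of labels as noise.  Because raw log2
expression and beta are both non-negative, the score is computed on
mean-centered causal columns so that both classes occur; without centering
the threshold would put nearly every sample in class 1.

``run_table2`` evaluates named design/penalty settings against the planted
truth: plain LASSO on the causal genes plus growing decoy sets, LASSO with
the causal genes excluded, and the informed-prior settings E1
(gamma = alpha ~ Unif(0,1) on causal genes) and E2 (gamma = 0 on causal
genes, i.e. unpenalized).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionDataset
from .evaluation import CVPlan, auc, nested_cv_fit  # noqa: F401 (CVPlan in signatures)
from .priors import PenaltyVector

__all__ = [
    "SyntheticTruth",
    "Table2Setting",
    "generate_expression",
    "sigmoid_label",
    "generate_outcome",
    "make_synthetic_dataset",
    "table2_presets",
    "run_table2",
]

logger = logging.getLogger(__name__)


@dataclass
class SyntheticTruth:
    """Ground truth of a planted synthetic outcome."""

    causal_genes: list[str]
    causal_idx: np.ndarray
    true_beta: np.ndarray  # k coefficients in [0, 1]
    flip_mask: np.ndarray  # indices of label-flipped samples
    flip_fraction: float
    seed: int

    @property
    def k(self) -> int:
        return len(self.causal_genes)

    def to_json(self, path) -> None:
        payload = {
            "causal_genes": list(self.causal_genes),
            "causal_idx": self.causal_idx.tolist(),
            "true_beta": self.true_beta.tolist(),
            "flip_mask": self.flip_mask.tolist(),
            "flip_fraction": self.flip_fraction,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            causal_genes=d["causal_genes"],
            causal_idx=np.asarray(d["causal_idx"], dtype=int),
            true_beta=np.asarray(d["true_beta"], dtype=float),
            flip_mask=np.asarray(d["flip_mask"], dtype=int),
            flip_fraction=d["flip_fraction"],
            seed=d["seed"],
        )


def generate_expression(
    n: int,
    p: int,
    block_size: int = 50,
    within_block_corr: float = 0.4,
    seed: int = 0,
    loc: float = 6.0,
    scale: float = 2.0,
) -> ExpressionDataset:
    """Log2-scale expression matrix with equicorrelated gene blocks.

    Consecutive groups of ``block_size`` genes share a latent factor giving
    pairwise correlation ``within_block_corr`` inside the block (the last
    block may be short); blocks are independent.  Values are
    ``loc + scale * z`` truncated at 0.  Labels are initialized to 0; use
    :func:`generate_outcome` to plant an outcome.
    """
    if not 0.0 <= within_block_corr < 1.0:
        raise ValueError("within_block_corr must lie in [0, 1)")
    if block_size < 1:
        raise ValueError("block_size must be positive")
    rng = np.random.default_rng(seed)
    Z = np.empty((n, p))
    rho = within_block_corr
    for start in range(0, p, block_size):
        width = min(block_size, p - start)
        shared = rng.standard_normal(n)[:, None]
        own = rng.standard_normal((n, width))
        Z[:, start : start + width] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
    X = np.maximum(loc + scale * Z, 0.0)
    return ExpressionDataset(
        matrix=X,
        gene_symbols=[f"G{j:05d}" for j in range(p)],
        labels=np.zeros(n, dtype=int),
        sample_ids=[f"S{i:04d}" for i in range(n)],
    )


def sigmoid_label(x_row, beta_full) -> int:
    """Binary label from the sigmoid threshold: 1 iff x . beta >= 0.

    The boundary sigmoid(0) = 0.5 maps to class 1.
    """
    x = np.asarray(x_row, dtype=float)
    b = np.asarray(beta_full, dtype=float)
    if x.shape != b.shape:
        raise ValueError("x_row and beta_full must have equal length")
    return int(x @ b >= 0.0)


def generate_outcome(
    ds: ExpressionDataset,
    k: int,
    flip_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Plant a sigmoid-threshold outcome on ``k`` random causal genes.

    Causal genes are drawn uniformly without replacement and their
    coefficients from Unif[0, 1].  The linear score uses mean-centered causal
    columns (see module docstring); exactly ``round(flip_fraction * n)``
    labels are then flipped at uniformly chosen samples.
    """
    n, p = ds.matrix.shape
    if k > p:
        raise ValueError(f"k={k} causal genes but only p={p} available")
    if not 0.0 <= flip_fraction < 0.5:
        raise ValueError("flip_fraction must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    causal_idx = np.sort(rng.choice(p, size=k, replace=False))
    true_beta = rng.uniform(0.0, 1.0, size=k)
    Xc = ds.matrix[:, causal_idx]
    Xc = Xc - Xc.mean(axis=0)
    labels = (Xc @ true_beta >= 0.0).astype(np.int8)
    n_flip = round(flip_fraction * n)
    flip_mask = rng.choice(n, size=n_flip, replace=False)
    labels[flip_mask] = 1 - labels[flip_mask]
    truth = SyntheticTruth(
        causal_genes=[ds.gene_symbols[j] for j in causal_idx],
        causal_idx=causal_idx,
        true_beta=true_beta,
        flip_mask=np.sort(flip_mask),
        flip_fraction=flip_fraction,
        seed=seed,
    )
    return labels, truth


def make_synthetic_dataset(
    n: int,
    p: int,
    k: int,
    block_size: int = 50,
    within_block_corr: float = 0.4,
    flip_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Expression matrix plus planted outcome in one call."""
    ds = generate_expression(
        n, p, block_size=block_size, within_block_corr=within_block_corr, seed=seed
    )
    labels, truth = generate_outcome(ds, k, flip_fraction=flip_fraction, seed=seed + 1)
    ds = ExpressionDataset(
        matrix=ds.matrix,
        gene_symbols=ds.gene_symbols,
        labels=labels,
        sample_ids=ds.sample_ids,
    )
    return ds, truth


@dataclass
class Table2Setting:
    """One design/penalty configuration of the planted-truth experiment.

    ``gene_pool`` selects the design columns: ``"truth+decoys"`` (causal
    genes plus ``n_decoys`` random non-causal ones), ``"all"``, or
    ``"exclude-truth"``.  ``gamma_rule`` sets penalty factors on the causal
    genes: ``"ones"`` (plain LASSO), ``"uniform-on-truth"``
    (alpha ~ Unif(0,1)), or ``"zero-on-truth"`` (unpenalized); non-causal
    genes always have gamma = 1.
    """

    name: str
    gene_pool: str = "all"
    n_decoys: int = 0
    gamma_rule: str = "ones"
    epsilon: float = 1.0


def table2_presets(scale: float = 1.0) -> list[Table2Setting]:
    """The six experiment settings, decoy counts scaled by ``scale``.

    At scale 1 the decoy counts are 100 and 1900, matching designs of
    100 + 100 and 100 + 1900 genes alongside the full and truth-excluded
    designs and the informed-prior settings E1/E2.
    """
    d1, d2 = max(1, round(100 * scale)), max(1, round(1900 * scale))
    return [
        Table2Setting("LASSO_truth+decoys100", "truth+decoys", d1, "ones"),
        Table2Setting("LASSO_truth+decoys1900", "truth+decoys", d2, "ones"),
        Table2Setting("LASSO_all", "all", 0, "ones"),
        Table2Setting("LASSO_minus_truth", "exclude-truth", 0, "ones"),
        Table2Setting("E1_BLASSO", "all", 0, "uniform-on-truth"),
        Table2Setting("E2_BLASSO", "all", 0, "zero-on-truth"),
    ]


def _setting_design(
    ds: ExpressionDataset,
    truth: SyntheticTruth,
    setting: Table2Setting,
    seed: int,
) -> tuple[ExpressionDataset, PenaltyVector, np.ndarray]:
    """Build the column subset and penalty vector for one setting."""
    p = ds.n_genes
    causal = truth.causal_idx
    rng = np.random.default_rng(seed)
    if setting.gene_pool == "truth+decoys":
        non_causal = np.setdiff1d(np.arange(p), causal)
        if setting.n_decoys > len(non_causal):
            raise ValueError("more decoys requested than non-causal genes")
        decoys = rng.choice(non_causal, size=setting.n_decoys, replace=False)
        pool = np.sort(np.concatenate([causal, decoys]))
    elif setting.gene_pool == "all":
        pool = np.arange(p)
    elif setting.gene_pool == "exclude-truth":
        pool = np.setdiff1d(np.arange(p), causal)
    else:
        raise ValueError(f"unknown gene_pool {setting.gene_pool!r}")
    sub = ds.subset_genes(pool)
    is_causal = np.isin(pool, causal)
    gamma = np.ones(len(pool))
    if setting.gamma_rule == "ones":
        pass
    elif setting.gamma_rule == "uniform-on-truth":
        gamma[is_causal] = rng.uniform(0.0, 1.0, size=int(is_causal.sum()))
    elif setting.gamma_rule == "zero-on-truth":
        gamma[is_causal] = 0.0
    else:
        raise ValueError(f"unknown gamma_rule {setting.gamma_rule!r}")
    pv = PenaltyVector.override(gamma, epsilon=setting.epsilon)
    return sub, pv, pool


def run_table2(
    ds: ExpressionDataset,
    truth: SyntheticTruth,
    settings: list[Table2Setting],
    plan: CVPlan,
    inner_K: int = 5,
    n_lambdas: int = 50,
    lambda_min_ratio: float | None = None,
    tol: float = 1e-4,
    seed: int = 12345,
) -> pd.DataFrame:
    """Cross-validated AUC and truth recovery for each setting.

    For every setting and every (repetition, fold) of ``plan``, lambda is
    tuned by inner CV on the training split (epsilon fixed by the setting),
    and the held-out fold yields the test AUC, the signature size (#genes)
    and its overlap with the planted causal set (#genes*).  Decoy sampling
    and the E1 alpha draw use fixed sub-seeds of ``seed``.
    """
    causal_set = set(truth.causal_genes)
    rows = []
    for s_i, setting in enumerate(settings):
        sub, pv, _pool = _setting_design(ds, truth, setting, seed + s_i)
        aucs, ngenes, nstar = [], [], []
        for r in range(plan.R):
            for train_idx, test_idx in plan.folds(r):
                train = sub.subset_samples(train_idx)
                sel = nested_cv_fit(
                    train,
                    gamma_builder=lambda eps, pv=pv: pv,
                    epsilon_grid=[setting.epsilon],
                    inner_K=inner_K,
                    seed=seed + 1009 * r,
                    n_lambdas=n_lambdas,
                    lambda_min_ratio=lambda_min_ratio,
                    tol=tol,
                    stratify=plan.stratified,
                )
                probs = sel.results.predict(sub.matrix[test_idx])
                aucs.append(auc(probs, sub.labels[test_idx]))
                sig = sel.results.signature
                ngenes.append(len(sig))
                nstar.append(len(sig & causal_set))
        rows.append(
            {
                "model": setting.name,
                "auc": float(np.mean(aucs)),
                "auc_sd": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
                "n_genes": float(np.mean(ngenes)),
                "n_genes_star": float(np.mean(nstar)),
            }
        )
        logger.info("setting %s: AUC %.4f, #genes %.1f, #genes* %.1f",
                    setting.name, rows[-1]["auc"], rows[-1]["n_genes"],
                    rows[-1]["n_genes_star"])
    return pd.DataFrame(rows)
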
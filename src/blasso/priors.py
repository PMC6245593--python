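"""Literature-derived penalty factors.

The prior on each gene is its citation record: a gene cited in many articles
is penalized less.  Counts come either from all literature mentioning the
gene (*gene-specific* mode) or only from articles that also mention a disease
of interest (*gene-disease* mode).  A count ``c`` becomes the L1 penalty
factor

    gamma = (1 / (c + 1)) ** epsilon,       epsilon in (0, 1]

so uncited genes keep the full penalty (gamma = 1) and heavily cited genes
approach 0; the exponent epsilon flattens the prior as it shrinks toward 0.

Association inputs are static text extracts (PubTator-style TSVs mapping
article IDs to gene symbols / disease terms) or a precomputed two-column
gene -> count table; no online access is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionDataset

__all__ = [
    "PriorError",
    "CitationTable",
    "PenaltyVector",
    "gamma_factor",
    "count_citations",
    "read_citation_counts",
    "build_penalty_vector",
]

GENE_SPECIFIC = "gene_specific"
GENE_DISEASE = "gene_disease"


class PriorError(ValueError):
    """Raised for invalid prior configuration or inputs."""


@dataclass
class CitationTable:
    """Mapping gene symbol -> number of distinct citing articles."""

    counts: dict[str, int]
    mode: str = GENE_SPECIFIC
    disease_context: str = ""

    def __post_init__(self) -> None:
        if self.mode not in (GENE_SPECIFIC, GENE_DISEASE):
            raise PriorError(f"unknown counting mode {self.mode!r}")
        if self.mode == GENE_DISEASE and not self.disease_context:
            raise PriorError("gene_disease mode requires a disease context")
        for g, c in self.counts.items():
            if int(c) != c or c < 0:
                raise PriorError(f"citation count for {g!r} must be a non-negative integer")
        # case-insensitive lookup key -> count
        self._folded = {str(g).strip().casefold(): int(c) for g, c in self.counts.items()}

    def lookup(self, symbol: str) -> int:
        """Count for a gene symbol; unmentioned genes have 0 citations."""
        return self._folded.get(str(symbol).strip().casefold(), 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_symbol": list(self.counts), "count": list(self.counts.values())}
        )


@dataclass
class PenaltyVector:
    """Per-gene L1 penalty factors aligned to a dataset's gene order.

    ``gamma[j] = 0`` means gene j is unpenalized, ``1`` fully penalized.
    Citation-derived vectors always lie in (0, 1]; explicit zeros are allowed
    only through :meth:`override` (used e.g. to leave known causal genes
    unpenalized).
    """

    gamma: np.ndarray
    epsilon: float = 1.0
    source: str = "explicit"

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if ((self.gamma < 0) | (self.gamma > 1)).any():
            raise PriorError("every penalty factor must lie in [0, 1]")

    @classmethod
    def ones(cls, p: int) -> "PenaltyVector":
        """Homogeneous priors: the standard-LASSO baseline."""
        return cls(np.ones(p), epsilon=1.0, source="uniform")

    @classmethod
    def override(cls, gamma, epsilon: float = 1.0) -> "PenaltyVector":
        """Explicit factors, including exact zeros (unpenalized genes)."""
        return cls(np.asarray(gamma, dtype=float), epsilon=epsilon, source="override")

    def __len__(self) -> int:
        return len(self.gamma)


def gamma_factor(cites: int, epsilon: float) -> float:
    """Penalty factor ``(1 / (cites + 1)) ** epsilon``.

    ``epsilon`` must lie in (0, 1].  Zero citations give exactly 1 (no
    down-weighting); the factor is strictly decreasing in the count.
    """
    if not 0.0 < epsilon <= 1.0:
        raise PriorError(f"epsilon must lie in (0, 1], got {epsilon}")
    if cites < 0:
        raise PriorError(f"citation count must be non-negative, got {cites}")
    return float((1.0 / (cites + 1.0)) ** epsilon)


def _read_assoc(path, col_name: str) -> pd.DataFrame:
    """Parse an (article_id, value[, ...]) TSV, skipping unparseable rows."""
    rows: list[tuple[str, str]] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                skipped += 1
                continue
            rows.append((parts[0].strip(), parts[1].strip()))
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} unparseable association rows")
    return pd.DataFrame(rows, columns=["article_id", col_name])


def count_citations(
    gene_assoc,
    mode: str = GENE_SPECIFIC,
    disease_assoc=None,
    disease_terms: list[str] | None = None,
) -> CitationTable:
    """Count distinct citing articles per gene from association extracts.

    ``gene_assoc`` rows carry (article_id, gene_symbol); extra columns are
    ignored.  In gene-specific mode the count is the number of distinct
    article IDs mentioning the gene.  In gene-disease mode an article
    contributes only if it also appears in ``disease_assoc`` with a term
    matching ``disease_terms`` (exact match after case-folding).  A gene
    mentioned several times within one article counts once.
    """
    if mode not in (GENE_SPECIFIC, GENE_DISEASE):
        raise PriorError(f"unknown counting mode {mode!r}")
    genes = _read_assoc(gene_assoc, "gene_symbol").drop_duplicates()
    context = ""
    if mode == GENE_DISEASE:
        if disease_assoc is None or not disease_terms:
            raise PriorError(
                "gene_disease mode requires a disease association file and terms"
            )
        terms = {t.strip().casefold() for t in disease_terms}
        diseases = _read_assoc(disease_assoc, "term")
        hit_ids = diseases.loc[
            diseases["term"].str.casefold().isin(terms), "article_id"
        ].unique()
        genes = genes[genes["article_id"].isin(set(hit_ids))]
        context = ";".join(sorted(terms))
    counts = genes.groupby("gene_symbol")["article_id"].nunique()
    return CitationTable(counts=counts.to_dict(), mode=mode, disease_context=context)


def read_citation_counts(path, mode: str = GENE_SPECIFIC, disease_context: str = "") -> CitationTable:
    """Read a precomputed two-column (gene_symbol, count) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_symbol", "count"],
                     dtype={"gene_symbol": str}, comment="#")
    # tolerate a header row
    first = str(df.iloc[0, 0]).casefold() if len(df) else ""
    if first in ("gene_symbol", "gene", "symbol"):
        df = df.iloc[1:]
    counts = {str(g): int(c) for g, c in zip(df["gene_symbol"], df["count"])}
    return CitationTable(counts=counts, mode=mode, disease_context=disease_context)


def write_citation_counts(table: CitationTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", header=False, index=False)


def build_penalty_vector(
    ds: ExpressionDataset, table: CitationTable, epsilon: float
) -> PenaltyVector:
    """Penalty factors for each gene of ``ds`` from a citation table.

    Matching is case-insensitive after whitespace stripping; genes absent
    from the table have zero citations, hence gamma = 1.
    """
    if not 0.0 < epsilon <= 1.0:
        raise PriorError(f"epsilon must lie in (0, 1], got {epsilon}")
    gamma = np.array(
        [gamma_factor(table.lookup(sym), epsilon) for sym in ds.gene_symbols]
    )
    return PenaltyVector(gamma, epsilon=epsilon, source=f"citations:{table.mode}")
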
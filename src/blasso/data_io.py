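"""Reading, writing and preprocessing of expression matrices.

Expression data arrive as delimited text (TSV/CSV) holding a samples x genes
matrix of non-negative RNA-Seq values (e.g. RSEM-normalized counts) together
with a binary outcome column.  Preprocessing drops genes with zero expression
in every sample and applies a ``log2(v + 1)`` transform; the pseudocount keeps
individual zero entries of retained genes finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "ExpressionDataset",
    "read_expression",
    "write_expression",
    "preprocess",
]


class DataError(ValueError):
    """Raised for malformed or inconsistent expression input."""


@dataclass
class ExpressionDataset:
    """Samples x genes expression matrix with binary outcome labels.

    Parameters
    ----------
    matrix : ndarray of shape (n_samples, n_genes)
        Expression values; log2 scale after :func:`preprocess`.
    gene_symbols : list of str
        Unique gene identifiers (HUGO symbols), one per column.
    labels : ndarray of shape (n_samples,)
        Binary outcome, 0 = control/alive, 1 = case/dead.
    sample_ids : list of str
        One identifier per row.
    """

    matrix: np.ndarray
    gene_symbols: list[str]
    labels: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise DataError("expression matrix must be two-dimensional")
        n, p = self.matrix.shape
        if len(self.gene_symbols) != p:
            raise DataError(
                f"{len(self.gene_symbols)} gene symbols for {p} matrix columns"
            )
        if len(self.labels) != n:
            raise DataError(f"{len(self.labels)} labels for {n} samples")
        dupes = _duplicates(self.gene_symbols)
        if dupes:
            raise DataError(f"duplicate gene symbols: {sorted(dupes)}")
        if not np.isin(self.labels, (0, 1)).all():
            raise DataError("labels must take values in {0, 1}")
        self.labels = self.labels.astype(np.int8)
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(n)]
        elif len(self.sample_ids) != n:
            raise DataError(f"{len(self.sample_ids)} sample ids for {n} samples")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def subset_genes(self, indices: np.ndarray | list[int]) -> "ExpressionDataset":
        """New dataset restricted to the given gene columns (order kept)."""
        idx = np.asarray(indices)
        return replace(
            self,
            matrix=self.matrix[:, idx],
            gene_symbols=[self.gene_symbols[i] for i in idx],
        )

    def subset_samples(self, indices: np.ndarray | list[int]) -> "ExpressionDataset":
        idx = np.asarray(indices)
        return replace(
            self,
            matrix=self.matrix[idx],
            labels=self.labels[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Samples-in-rows DataFrame including the ``label`` column."""
        df = pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.gene_symbols)
        df.insert(0, "label", self.labels)
        return df


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup


def read_expression(
    path,
    label_column: str = "label",
    orientation: str = "samples-in-rows",
    sep: str = "\t",
) -> ExpressionDataset:
    """Read a delimited expression file into an :class:`ExpressionDataset`.

    The file must have a header row.  With ``orientation="samples-in-rows"``
    each row is a sample and one column (``label_column``) holds the binary
    outcome.  With ``orientation="genes-in-rows"`` each row is a gene, columns
    are samples, and the label row is named ``label_column`` in the first
    column; the matrix is transposed so that returned rows are always samples.
    No auto-detection is attempted: silent transposition is a classic bug
    source.
    """
    if orientation not in ("samples-in-rows", "genes-in-rows"):
        raise DataError(f"unknown orientation {orientation!r}")
    if orientation == "samples-in-rows":
        # pandas silently renames duplicate header fields; check the raw line
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        dupes = _duplicates(header)
        if dupes:
            raise DataError(f"duplicate gene symbols: {sorted(dupes)}")
    try:
        df = pd.read_csv(path, sep=sep, header=0, index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.; pandas names the line
        raise DataError(f"could not parse {path}: {exc}") from exc
    if orientation == "genes-in-rows":
        df = df.T
    if label_column not in df.columns:
        raise DataError(f"label column {label_column!r} not found")
    labels_raw = df[label_column]
    if not labels_raw.isin([0, 1]).all():
        bad = sorted(set(labels_raw) - {0, 1})
        raise DataError(f"label column {label_column!r} is not binary: {bad}")
    genes = [str(c) for c in df.columns if c != label_column]
    dupes = _duplicates(genes)
    if dupes:
        raise DataError(f"duplicate gene symbols: {sorted(dupes)}")
    return ExpressionDataset(
        matrix=df[genes].to_numpy(dtype=float),
        gene_symbols=genes,
        labels=labels_raw.to_numpy(),
        sample_ids=[str(i) for i in df.index],
    )


def write_expression(ds: ExpressionDataset, path, sep: str = "\t") -> None:
    """Write samples-in-rows delimited text, label column first."""
    ds.to_frame().to_csv(path, sep=sep, index_label="sample_id")


def preprocess(
    ds: ExpressionDataset, already_log2: bool = False
) -> tuple[ExpressionDataset, int]:
    """Drop all-zero genes and log2-transform.

    Genes with zero expression in every sample carry no predictive signal and
    are removed first.  Unless ``already_log2``, remaining values are mapped
    ``v -> log2(v + 1)``; raw values must then be non-negative.

    Returns
    -------
    (dataset, n_dropped)
        The preprocessed dataset and the number of genes removed.
    """
    X = ds.matrix
    if not already_log2 and (X < 0).any():
        raise DataError("negative raw expression values cannot be log-transformed")
    keep = ~(X == 0).all(axis=0)
    n_dropped = int((~keep).sum())
    out = ds.subset_genes(np.flatnonzero(keep))
    if not already_log2:
        out = replace(out, matrix=np.log2(out.matrix + 1.0))
    return out, n_dropped
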
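"""Core in-memory containers shared across the pipeline.

All matrices are oriented genes x cells, matching the 10x Matrix Market
triplet convention (genes as rows). Count matrices may be dense integer
arrays or any scipy sparse matrix; expression matrices are always dense
float arrays because the downstream Gaussian entropy model needs per-gene
moments and PCA on the full matrix anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


def _check_ids(ids: np.ndarray, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if ids.ndim != 1:
        raise ValueError(f"{what} ids must be one-dimensional")
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} ids must be unique")
    return ids


@dataclass
class CountMatrix:
    """Raw gene x cell integer counts with identifiers.

    Parameters
    ----------
    counts
        Non-negative integer matrix of shape (n_genes, n_cells); dense
        ndarray or scipy sparse.
    gene_ids, cell_ids
        Unique string identifiers for rows and columns.
    """

    counts: "np.ndarray | sp.spmatrix"
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def min(self) -> float:
        if sp.issparse(self.counts):
            return min(0.0, self.counts.data.min()) if self.counts.nnz else 0.0
        return float(self.counts.min()) if self.counts.size else 0.0

    def dense(self) -> np.ndarray:
        """Counts as a dense ndarray (copy-free for dense input)."""
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)

    def genes_per_cell(self) -> np.ndarray:
        """Number of genes with nonzero count, per cell."""
        if sp.issparse(self.counts):
            return np.asarray((self.counts != 0).sum(axis=0)).ravel()
        return np.count_nonzero(self.counts, axis=0)

    def cells_per_gene(self) -> np.ndarray:
        """Number of cells with nonzero count, per gene."""
        if sp.issparse(self.counts):
            return np.asarray((self.counts != 0).sum(axis=1)).ravel()
        return np.count_nonzero(self.counts, axis=1)


@dataclass
class ExprMatrix:
    """Log-normalized gene x cell expression (natural-log scale, nats)."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    normalization_record: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("values shape does not match id lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_genes(self, gene_ids) -> "ExprMatrix":
        """Row subset in the given gene order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExprMatrix(
            self.values[rows],
            np.asarray(list(gene_ids), dtype=object),
            self.cell_ids,
            dict(self.normalization_record),
        )


@dataclass
class PCEmbedding:
    """Principal-component scores of cells, the reduced environment Z.

    The scores summarise "all other genes" for the conditional-entropy
    computation: each cell is represented by its projection onto the top
    ``n_pcs`` principal axes of the gene-centered expression matrix.
    """

    scores: np.ndarray            # cells x n_pcs
    n_pcs: int
    explained_variance: np.ndarray
    centering_record: np.ndarray  # per-gene means removed before the SVD
    cell_ids: np.ndarray
    loadings: np.ndarray          # n_pcs x genes, orthonormal rows

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.cell_ids), self.n_pcs):
            raise ValueError("scores shape does not match cell list / n_pcs")


@dataclass
class FeatureSet:
    """An ordered gene selection produced by one selection method."""

    gene_ids: list
    k: int
    method_tag: str

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("feature set contains duplicate genes")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)


@dataclass
class ClusterLabels:
    """Integer partition of cells, labels in 1..k_clusters."""

    cell_ids: np.ndarray
    label: np.ndarray
    k_clusters: int

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=np.int64)
        if len(self.label) != len(self.cell_ids):
            raise ValueError("one label per cell required")
        if len(self.label) and (self.label.min() < 1 or self.label.max() > self.k_clusters):
            raise ValueError("labels must lie in [1, k_clusters]")
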
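"""Quality filtering and log-normalization of count matrices.

The entropy model assumes approximately Gaussian log-normalized
expression, so counts are scaled per cell to a common total (size-factor
normalization, default 10^4) and transformed with the natural log1p.
Filtering thresholds default to the conventions used for droplet data:
genes seen in fewer than 10 cells and cells expressing fewer than 600
genes are removed.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .containers import CountMatrix, ExprMatrix


class EmptyMatrixError(ValueError):
    """Raised when a filter would leave no genes or no cells."""


def filter_genes(m: CountMatrix, min_cells: int = 10) -> CountMatrix:
    """Keep genes detected (count > 0) in at least ``min_cells`` cells.

    Gene order is preserved; the cell set is untouched. ``min_cells=0``
    returns the input unchanged.
    """
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    if min_cells == 0:
        return m
    keep = m.cells_per_gene() >= min_cells
    if not keep.any():
        raise EmptyMatrixError(f"no genes detected in >= {min_cells} cells survive")
    counts = m.counts[keep] if not sp.issparse(m.counts) else m.counts.tocsr()[np.flatnonzero(keep)]
    return CountMatrix(counts, m.gene_ids[keep], m.cell_ids)


def filter_cells(m: CountMatrix, min_genes: int = 600) -> CountMatrix:
    """Keep cells expressing at least ``min_genes`` genes at nonzero count."""
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    if min_genes == 0:
        return m
    keep = m.genes_per_cell() >= min_genes
    if not keep.any():
        raise EmptyMatrixError(f"no cells expressing >= {min_genes} genes survive")
    counts = m.counts[:, keep] if not sp.issparse(m.counts) else m.counts.tocsc()[:, np.flatnonzero(keep)].tocsr()
    return CountMatrix(counts, m.gene_ids, m.cell_ids[keep])


def normalize_log(m: CountMatrix, scale: float = 1e4) -> ExprMatrix:
    """Size-factor normalize to ``scale`` counts per cell, then log1p.

    value(g, c) = ln(1 + scale * count(g, c) / total(c)), natural log, so
    downstream entropies are in nats. Each cell must have a positive
    total count; filter empty cells first.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    counts = m.dense().astype(np.float64)
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        n_empty = int((totals <= 0).sum())
        raise ValueError(
            f"{n_empty} cell(s) have zero total count; run filter_cells first"
        )
    values = np.log1p(scale * counts / totals[None, :])
    record = {"method": "size_factor_log1p", "scale": float(scale), "log_base": "e"}
    return ExprMatrix(values, m.gene_ids, m.cell_ids, record)
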
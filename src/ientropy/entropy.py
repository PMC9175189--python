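"""Differential-entropy decomposition of per-gene expression fluctuation.

Under a multivariate-normal model of log-normalized expression, the total
entropy (TE) of a gene x splits exactly into the mutual information
between x and the rest of the transcriptome Z — the extrinsic entropy
(EE) — and the conditional entropy of x given Z — the intrinsic entropy
(IE):

    TE(x) = H(x) = MI(x, Z) + H(x | Z) = EE(x) + IE(x)

EE captures fluctuation imposed on the gene by its environment (shared,
"noisy" structure); IE is what remains once that environment is
conditioned away, and is the informativeness score used for feature
selection. With Gaussian marginals all three have closed forms in sample
(co)variances: TE = 1/2 ln(2*pi*e*var(x)) and

    IE = 1/2 (ln 2*pi + 1) + 1/2 ln(|Sigma_{x,Z}| / |Sigma_Z|)
       = 1/2 ln(2*pi*e * sigma^2_{x|Z}),

where sigma^2_{x|Z} = var(x) - Sigma_xZ Sigma_Z^{-1} Sigma_Zx is the
Schur complement (conditional variance). The full transcriptome Z is
replaced by the top principal components of the expression matrix, which
makes the k x k solve cheap and shared across genes.

All entropies are differential entropies in nats. Covariances use the
unbiased (n - 1) denominator throughout so the Schur complement and
determinant-ratio forms agree exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExprMatrix, PCEmbedding

#: 1/2 (ln 2*pi + 1): entropy of a unit-variance Gaussian, nats.
GAUSSIAN_UNIT_ENTROPY = 0.5 * (np.log(2.0 * np.pi) + 1.0)

#: Relative floor under which a conditional variance is treated as zero
#: (the gene is perfectly predictable from Z and has no finite IE).
CONDITIONAL_VARIANCE_FLOOR = 1e-12

_JITTER_SCALE = 1e-10
_MAX_JITTER_TRIES = 3


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    """Covariance has a negative eigenvalue beyond the jitter tolerance."""


def _chol_logdet(cov: np.ndarray) -> float:
    """log|cov| via Cholesky, with diagonal jitter retries for PSD inputs."""
    cov = np.asarray(cov, dtype=np.float64)
    d = cov.shape[0]
    jitter = _JITTER_SCALE * np.trace(cov) / d
    shift = 0.0
    for attempt in range(_MAX_JITTER_TRIES + 1):
        try:
            chol = np.linalg.cholesky(cov + shift * np.eye(d))
        except np.linalg.LinAlgError:
            shift = jitter * (10.0 ** attempt)
            continue
        return 2.0 * float(np.sum(np.log(np.diag(chol))))
    raise NotPositiveDefiniteError(
        "covariance is not positive definite within jitter tolerance"
    )


def gaussian_entropy(cov) -> float:
    """Differential entropy (nats) of N(mu, cov): d/2 (ln 2*pi + 1) + 1/2 ln|cov|.

    ``cov`` may be a scalar variance, a length-1 array, or a symmetric
    positive-(semi)definite matrix. Raises
    :class:`NotPositiveDefiniteError` if the matrix has a negative
    eigenvalue beyond a tiny diagonal-jitter tolerance.
    """
    cov = np.atleast_2d(np.asarray(cov, dtype=np.float64))
    d = cov.shape[0]
    if cov.shape != (d, d):
        raise ValueError("cov must be square")
    tol = 1e-8 * max(1.0, float(np.abs(cov).max()))
    if np.abs(cov - cov.T).max() > tol:
        raise ValueError("cov must be symmetric")
    return d * GAUSSIAN_UNIT_ENTROPY + 0.5 * _chol_logdet(cov)


def compute_pcs(expr: ExprMatrix, n_pcs: int = 20) -> PCEmbedding:
    """Top-``n_pcs`` principal-component scores of cells.

    PCA is fit on the gene-centered (not scaled) expression matrix with
    cells as observations; scaling is deliberately avoided because it
    would equalize the per-gene variances the entropy model ranks.
    Output is deterministic: each component's loading vector is flipped
    so that its largest-magnitude entry is positive.
    """
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    max_pcs = min(expr.n_genes, expr.n_cells) - 1
    if n_pcs > max_pcs:
        raise ValueError(
            f"n_pcs={n_pcs} exceeds the attainable maximum {max_pcs} "
            f"for {expr.n_genes} genes x {expr.n_cells} cells"
        )
    gene_means = expr.values.mean(axis=1)
    centered = (expr.values - gene_means[:, None]).T  # cells x genes
    if np.count_nonzero(expr.values.std(axis=1) > 0) < 2:
        raise ValueError("need at least 2 genes with nonzero variance")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    u, s, vt = u[:, :n_pcs], s[:n_pcs], vt[:n_pcs]
    # sign convention: largest-magnitude loading entry positive
    flip = np.sign(vt[np.arange(n_pcs), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    return PCEmbedding(
        scores=u * s,
        n_pcs=n_pcs,
        explained_variance=s**2 / max(expr.n_cells - 1, 1),
        centering_record=gene_means,
        cell_ids=expr.cell_ids,
        loadings=vt,
    )


def total_entropy(expr: ExprMatrix) -> np.ndarray:
    """Per-gene TE = 1/2 ln(2*pi*e*var), nats; NaN for zero-variance genes."""
    var = expr.values.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        te = GAUSSIAN_UNIT_ENTROPY + 0.5 * np.log(var)
    te[var <= 0] = np.nan
    return te


def _moments(expr: ExprMatrix, pcs: PCEmbedding):
    if expr.n_cells != len(pcs.cell_ids) or not np.array_equal(expr.cell_ids, pcs.cell_ids):
        raise ValueError("expr and pcs must cover the same cells in the same order")
    n = expr.n_cells
    if n < 3:
        raise ValueError("need at least 3 cells")
    xc = expr.values - expr.values.mean(axis=1, keepdims=True)
    zc = pcs.scores - pcs.scores.mean(axis=0, keepdims=True)
    var = (xc**2).sum(axis=1) / (n - 1)
    cov_z = zc.T @ zc / (n - 1)
    cross = xc @ zc / (n - 1)  # genes x n_pcs
    return var, cov_z, cross


def _rank_table(expr: ExprMatrix, te, ie, degenerate) -> pd.DataFrame:
    ee = te - ie
    n = expr.n_genes
    order = np.full(n, -1, dtype=np.int64)
    scored = np.flatnonzero(~degenerate)
    # stable sort by descending IE; ties keep input gene order
    scored_sorted = scored[np.argsort(-ie[scored], kind="stable")]
    order[: scored_sorted.size] = scored_sorted
    order[scored_sorted.size:] = np.flatnonzero(degenerate)
    table = pd.DataFrame(
        {
            "gene_id": expr.gene_ids[order],
            "te": te[order],
            "ee": ee[order],
            "ie": ie[order],
            "rank": np.arange(1, n + 1),
            "degenerate": degenerate[order],
        }
    )
    return table.reset_index(drop=True)


def intrinsic_entropy(
    expr: ExprMatrix, pcs: PCEmbedding, method: str = "schur"
) -> pd.DataFrame:
    """Per-gene entropy decomposition table, ranked by descending IE.

    For each gene x with sample variance var(x) and cross-covariance c
    to the PC scores Z:

    - ``method="schur"`` computes the conditional variance
      var(x) - c Sigma_Z^{-1} c^T directly (one shared k x k solve).
    - ``method="det"`` evaluates the equivalent determinant ratio
      |Sigma_{x,Z}| / |Sigma_Z| per gene via log-determinants.

    The two are algebraically identical and serve as mutual checks.

    Returns a DataFrame with columns gene_id, te, ee, ie, rank,
    degenerate, sorted by rank. Genes with zero variance or with
    conditional variance below ``CONDITIONAL_VARIANCE_FLOOR * var`` are
    flagged degenerate (NaN entropies) and ranked after all scored genes
    in input order.
    """
    var, cov_z, cross = _moments(expr, pcs)
    zero_var = var <= 0

    if method == "schur":
        solved = np.linalg.solve(cov_z, cross.T)  # n_pcs x genes
        explained = np.einsum("gk,kg->g", cross, solved)
        cond = var - explained
    elif method == "det":
        logdet_z = _chol_logdet(cov_z)
        cond = np.empty_like(var)
        k = cov_z.shape[0]
        joint = np.empty((k + 1, k + 1))
        joint[1:, 1:] = cov_z
        for g in range(var.size):
            if zero_var[g]:
                cond[g] = 0.0
                continue
            joint[0, 0] = var[g]
            joint[0, 1:] = cross[g]
            joint[1:, 0] = cross[g]
            cond[g] = np.exp(_chol_logdet(joint) - logdet_z)
    else:
        raise ValueError(f"unknown method {method!r}; use 'schur' or 'det'")

    degenerate = zero_var | (cond < CONDITIONAL_VARIANCE_FLOOR * var)
    with np.errstate(divide="ignore", invalid="ignore"):
        te = GAUSSIAN_UNIT_ENTROPY + 0.5 * np.log(var)
        ie = GAUSSIAN_UNIT_ENTROPY + 0.5 * np.log(cond)
    te[degenerate] = np.nan
    ie[degenerate] = np.nan
    return _rank_table(expr, te, ie, degenerate)


def intrinsic_entropy_loo(expr: ExprMatrix, n_pcs: int = 20) -> pd.DataFrame:
    """Leave-one-out variant: refit the PC environment excluding each gene.

    The shared-embedding approximation in :func:`intrinsic_entropy` keeps
    gene x inside the PCA that defines its own environment; this exact
    variant removes it first, at the cost of one PCA per gene. Intended
    for small matrices only (quantifying the approximation error).
    """
    records = []
    all_genes = list(expr.gene_ids)
    for g in all_genes:
        others = [h for h in all_genes if h != g]
        sub = expr.subset_genes(others)
        pcs = compute_pcs(sub, n_pcs=n_pcs)
        one = expr.subset_genes([g])
        row = intrinsic_entropy(one, pcs).iloc[0]
        records.append(row)
    table = pd.DataFrame(records).reset_index(drop=True)
    return _rank_table(
        expr,
        te=table["te"].to_numpy(),
        ie=table["ie"].to_numpy(),
        degenerate=table["degenerate"].to_numpy(dtype=bool),
    )


def extrinsic_entropy(table: pd.DataFrame) -> pd.Series:
    """EE column (te - ie per gene); exposed for API symmetry."""
    return table["te"] - table["ie"]
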
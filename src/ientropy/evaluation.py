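"""Clustering-based benchmark of feature-selection quality.

The benchmark follows the standard simulation design: draw labeled
counts, preprocess, score genes, select feature sets with competing
methods, cluster cells on each set, and compare the partitions with the
ground truth via the adjusted Rand index (ARI). The ARI is implemented
from its contingency-table definition rather than delegated, since it is
the benchmark's measuring instrument.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import ClusterLabels, ExprMatrix, FeatureSet
from .entropy import compute_pcs, intrinsic_entropy
from .preprocess import filter_cells, filter_genes, normalize_log
from .selection import select_by_variance, select_random, select_top
from .sim import SimParams, simulate_counts

BENCHMARK_METHODS = ("ie", "te", "variance", "random")


def de_recovery_study(
    params: SimParams,
    n_replicates: int = 20,
    gene_count: int = 200,
    n_pcs: int = 20,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Signal-recovery study: does IE rank and select DE genes?

    For each replicate (seed derived from ``params.seed``): simulate,
    filter, normalize, score entropies, then record (i) the median IE of
    truly differentially expressed genes minus the median IE of non-DE
    genes, and (ii) the ARI of k-means clustering on the top
    ``gene_count`` IE genes versus on ``gene_count`` random genes, both
    against the simulated group labels (paired per seed).

    Returns one row per replicate with columns seed, median_ie_de,
    median_ie_non_de, ari_ie, ari_random.
    """
    from .selection import select_random as _select_random
    from .selection import select_top as _select_top

    rows = []
    k_true = len(params.group_proportions)
    for rep in range(n_replicates):
        sim_seed = _stage_seed(params.seed, 0, rep)
        counts, truth = simulate_counts(replace(params, seed=sim_seed))
        kept = filter_genes(counts, min_cells=min_cells)
        de_map = dict(zip(counts.gene_ids, truth.de_flag))
        expr = normalize_log(kept)
        pcs = compute_pcs(expr, n_pcs=n_pcs)
        table = intrinsic_entropy(expr, pcs)
        scored = table.loc[~table["degenerate"]]
        de_mask = scored["gene_id"].map(de_map).astype(bool)
        truth_labels = ClusterLabels(kept.cell_ids, truth.cell_group, k_true)
        aris = {}
        for tag, feats in (
            ("ie", _select_top(table, k=gene_count)),
            ("random", _select_random(
                list(expr.gene_ids), k=min(gene_count, expr.n_genes),
                seed=_stage_seed(params.seed, 1, rep))),
        ):
            labels = cluster_cells(
                expr, feats, n_pcs=n_pcs, k_clusters=k_true,
                seed=_stage_seed(params.seed, 2, rep),
            )
            aris[tag] = adjusted_rand_index(labels, truth_labels)
        rows.append({
            "seed": rep,
            "median_ie_de": float(scored.loc[de_mask, "ie"].median()),
            "median_ie_non_de": float(scored.loc[~de_mask, "ie"].median()),
            "ari_ie": aris["ie"],
            "ari_random": aris["random"],
        })
    return pd.DataFrame(rows)


def adjusted_rand_index(a: ClusterLabels, b: ClusterLabels) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions.

    From the contingency table N with row sums a_i and column sums b_j:

        ARI = (S - E) / (M - E),  S = sum_ij C(n_ij, 2),
        E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2),
        M = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2.

    Returns 1 whenever the two partitions agree on every cell pair
    (covering the degenerate identical-trivial case where the general
    formula is 0/0); the remaining E = M case returns 0 by convention.
    """
    if len(a.label) != len(b.label):
        raise ValueError("partitions must cover the same cells")
    n = len(a.label)
    if n < 2:
        raise ValueError("need at least 2 cells")
    if not np.array_equal(a.cell_ids, b.cell_ids):
        raise ValueError("partitions must list cells in the same order")

    def comb2(x):
        return x * (x - 1) / 2.0

    _, ai = np.unique(a.label, return_inverse=True)
    _, bi = np.unique(b.label, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(table, (ai, bi), 1)
    s = comb2(table).sum()
    row = comb2(table.sum(axis=1)).sum()
    col = comb2(table.sum(axis=0)).sum()
    if s == row == col:
        return 1.0  # every pair classified identically
    expected = row * col / comb2(n)
    mean_index = (row + col) / 2.0
    if mean_index == expected:
        return 0.0
    return float((s - expected) / (mean_index - expected))


def cluster_cells(
    expr: ExprMatrix,
    features: FeatureSet,
    n_pcs: int = 20,
    k_clusters: int = 2,
    seed: int = 0,
) -> ClusterLabels:
    """Seeded k-means on the top PCs of the feature-subset expression.

    If the feature subset supports fewer than ``n_pcs`` components, the
    count is reduced with a warning rather than failing.
    """
    if k_clusters < 1:
        raise ValueError("k_clusters must be >= 1")
    sub = expr.subset_genes(list(features))
    if k_clusters == 1:
        return ClusterLabels(expr.cell_ids, np.ones(expr.n_cells, dtype=np.int64), 1)
    max_pcs = min(sub.n_genes, sub.n_cells) - 1
    if n_pcs > max_pcs:
        warnings.warn(f"reducing n_pcs from {n_pcs} to attainable {max_pcs}")
        n_pcs = max_pcs
    pcs = compute_pcs(sub, n_pcs=n_pcs)
    km = KMeans(n_clusters=k_clusters, n_init=10, max_iter=300, random_state=seed)
    labels = km.fit_predict(pcs.scores) + 1
    return ClusterLabels(expr.cell_ids, labels, k_clusters)


def _stage_seed(base_seed: int, *key) -> int:
    """Deterministic sub-seed below 2**31 derived from a base seed."""
    ss = np.random.SeedSequence([int(base_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] >> 1)


def benchmark_feature_selection(
    params: SimParams,
    gene_counts=(200, 500, 1000),
    methods=BENCHMARK_METHODS,
    n_replicates: int = 20,
    n_pcs: int = 20,
    min_cells: int = 10,
    min_genes: int = 0,
) -> pd.DataFrame:
    """Full-factorial ARI benchmark over methods x gene counts x replicates.

    Per replicate: simulate counts (seed derived from ``params.seed`` and
    the replicate index), filter, log-normalize, score entropies, then
    for each method and feature-set size cluster the cells with k-means
    (k = number of true groups, same n_pcs as the entropy environment)
    and record ARI against the simulated group labels.

    ``min_genes`` defaults to 0 here because simulated matrices are
    desk-scale (a 600-gene cell filter is calibrated to full
    transcriptomes); pass a positive value to enable the cell filter.

    Returns a DataFrame with columns method, gene_count, seed, ari and
    exactly len(methods) * len(gene_counts) * n_replicates rows.
    """
    unknown = set(methods) - set(BENCHMARK_METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; choose from {BENCHMARK_METHODS}")
    rows = []
    k_true = len(params.group_proportions)
    for rep in range(n_replicates):
        sim_seed = _stage_seed(params.seed, 0, rep)
        counts, truth = simulate_counts(replace(params, seed=sim_seed))
        kept = filter_genes(counts, min_cells=min_cells)
        if min_genes > 0:
            kept = filter_cells(kept, min_genes=min_genes)
        cell_keep = np.isin(counts.cell_ids, kept.cell_ids)
        true_labels = ClusterLabels(
            kept.cell_ids, truth.cell_group[cell_keep], k_true
        )
        expr = normalize_log(kept)
        pcs = compute_pcs(expr, n_pcs=n_pcs)
        table = intrinsic_entropy(expr, pcs)
        for method in methods:
            for k_genes in gene_counts:
                if method in ("ie", "te"):
                    feats = select_top(table, k=k_genes, by=method)
                elif method == "variance":
                    feats = select_by_variance(expr, k=k_genes)
                else:
                    feats = select_random(
                        expr.gene_ids, k=min(k_genes, expr.n_genes),
                        seed=_stage_seed(params.seed, 1, rep, k_genes),
                    )
                try:
                    labels = cluster_cells(
                        expr, feats, n_pcs=n_pcs, k_clusters=k_true,
                        seed=_stage_seed(params.seed, 2, rep, k_genes),
                    )
                    ari = adjusted_rand_index(labels, true_labels)
                except Exception as err:
                    raise RuntimeError(
                        f"benchmark stage failed (seed={sim_seed}, method={method}, "
                        f"gene_count={k_genes})"
                    ) from err
                rows.append(
                    {"method": method, "gene_count": k_genes, "seed": rep, "ari": ari}
                )
    return pd.DataFrame(rows)
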
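"""Feature-gene selection from the entropy table, plus the PIE statistic."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import ExprMatrix, FeatureSet


def select_top(table: pd.DataFrame, k: int, by: str = "ie") -> FeatureSet:
    """Top-``k`` non-degenerate genes by descending ``by`` in {"ie", "te"}.

    Ties are broken by input gene order (stable sort). If fewer than
    ``k`` genes are available the set is truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if by not in ("ie", "te"):
        raise ValueError(f"invalid ranking column {by!r}; use 'ie' or 'te'")
    scored = table.loc[~table["degenerate"].astype(bool)]
    if by == "ie":
        # table rows are already in rank order (descending IE, stable ties)
        chosen = scored
    else:
        chosen = scored.iloc[np.argsort(-scored[by].to_numpy(), kind="stable")]
    if k > len(chosen):
        warnings.warn(
            f"requested k={k} but only {len(chosen)} non-degenerate genes; truncating"
        )
    return FeatureSet(list(chosen["gene_id"].iloc[:k]), k=k, method_tag=by)


def select_random(gene_ids, k: int, seed: int) -> FeatureSet:
    """Uniform sample of ``k`` genes without replacement, seeded."""
    gene_ids = list(gene_ids)
    if not 1 <= k <= len(gene_ids):
        raise ValueError(f"k must be in [1, {len(gene_ids)}]")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(gene_ids), size=k, replace=False)
    return FeatureSet([gene_ids[i] for i in picked], k=k, method_tag="random")


def select_by_variance(expr: ExprMatrix, k: int) -> FeatureSet:
    """Top-``k`` genes by sample variance of log-normalized expression.

    A simple dispersion baseline: high total variance, regardless of how
    much of it is shared with the rest of the transcriptome.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    var = expr.values.var(axis=1, ddof=1)
    order = np.argsort(-var, kind="stable")
    k_eff = min(k, expr.n_genes)
    if k > k_eff:
        warnings.warn(f"requested k={k} but only {k_eff} genes; truncating")
    return FeatureSet([expr.gene_ids[i] for i in order[:k_eff]], k=k, method_tag="variance")


def pie_statistic(table: pd.DataFrame, marker_genes, k: int = 10) -> float:
    """Proportion of top intrinsic entropy captured by a marker set.

    PIE = (sum of IE over the top-``k`` markers, markers ranked by IE)
        / (sum of IE over the global top-``k`` IE genes).

    A marker set that coincides with the globally most informative genes
    scores 1; uninformative markers score near 0. If fewer than ``k``
    markers exist, the numerator sums over all of them while the
    denominator keeps ``k`` terms, so the value stays in [0, 1] whenever
    all summed IE values are nonnegative. Genes with negative IE
    (near-degenerate under differential entropy) are excluded from both
    sums to preserve that range.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    marker_genes = set(marker_genes)
    if not marker_genes:
        raise ValueError("marker_genes must be non-empty")
    scored = table.loc[~table["degenerate"].astype(bool) & (table["ie"] >= 0)]
    present = scored.loc[scored["gene_id"].isin(marker_genes), "ie"]
    if not table["gene_id"].isin(marker_genes).any():
        raise KeyError("no marker gene present in the entropy table")
    # rows are in rank order, so head() takes the highest-IE entries
    numerator = float(present.head(k).sum())
    denominator = float(scored["ie"].head(k).sum())
    if denominator <= 0:
        raise ValueError("global top-k IE sum is nonpositive; PIE undefined")
    return numerator / denominator
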
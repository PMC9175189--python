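import numpy as np
import pytest

import ientropy as ie


@pytest.fixture(scope="session")
def small_sim():
    """One desk-scale simulated dataset shared across read-only tests."""
    params = ie.SimParams(seed=42)
    counts, truth = ie.simulate_counts(params)
    return params, counts, truth


@pytest.fixture(scope="session")
def scored_expr(small_sim):
    """Filtered, normalized and entropy-scored version of small_sim."""
    _, counts, truth = small_sim
    kept = ie.filter_genes(counts, min_cells=10)
    expr = ie.normalize_log(kept)
    pcs = ie.compute_pcs(expr, n_pcs=20)
    table = ie.intrinsic_entropy(expr, pcs)
    return expr, pcs, table, truth


def make_correlated_gene_fixture(rho: float, n_cells: int = 200, seed: int = 0):
    """ExprMatrix + 1-PC embedding with exact sample correlation rho.

    The gene is built from an orthonormalized noise component so that its
    empirical correlation with the PC score vector equals rho to machine
    precision, giving a closed-form mutual information -0.5*ln(1-rho^2).
    """
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n_cells)
    e = rng.normal(size=n_cells)
    z = z - z.mean()
    z = z / np.sqrt((z**2).sum() / (n_cells - 1))
    e = e - e.mean()
    e = e - z * ((e * z).sum() / (z**2).sum())  # exact sample orthogonality
    e = e / np.sqrt((e**2).sum() / (n_cells - 1))
    x = rho * z + np.sqrt(1.0 - rho**2) * e
    cell_ids = np.array([f"c{i}" for i in range(n_cells)], dtype=object)
    expr = ie.ExprMatrix(x[None, :], np.array(["g1"], dtype=object), cell_ids)
    pcs = ie.PCEmbedding(
        scores=z[:, None],
        n_pcs=1,
        explained_variance=np.array([1.0]),
        centering_record=np.zeros(1),
        cell_ids=cell_ids,
        loadings=np.ones((1, 1)),
    )
    return expr, pcs
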
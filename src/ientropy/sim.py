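"""Gamma-Poisson scRNA-seq count simulator with group structure.

The generative hierarchy mirrors the Splatter family of simulators at its
core: a gamma-distributed baseline mean per gene, multiplicative group-
specific differential-expression (DE) factors, log-normal cell library
sizes, Poisson sampling, and optional logistic dropout. Marginally a
non-DE gene is therefore gamma-Poisson (negative binomial) across cells.

Ground truth (group label per cell, DE flag and factors per gene) is
returned alongside the counts so that feature-selection methods can be
benchmarked without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.io import mmwrite
from scipy.special import expit

from .containers import CountMatrix

#: Cell-group ratio of the five simulated populations (25:75:100:100:200).
DEFAULT_GROUP_RATIO = (25, 75, 100, 100, 200)


def ratio_to_proportions(ratio) -> tuple:
    """Normalize a positive ratio vector to proportions summing to 1.

    >>> ratio_to_proportions((25, 75, 100, 100, 200))
    (0.05, 0.15, 0.2, 0.2, 0.4)
    """
    r = np.asarray(ratio, dtype=float).ravel()
    if r.size == 0:
        raise ValueError("ratio must be non-empty")
    if np.any(r <= 0):
        raise ValueError("ratio entries must be strictly positive")
    p = r / r.sum()
    return tuple(p.tolist())


@dataclass(frozen=True)
class SimParams:
    """Parameters of the gamma-Poisson group simulation.

    Defaults describe a desk-scale version of a five-group droplet
    dataset: 500 cells split 25:75:100:100:200 over 2000 genes. Baseline
    gene means follow Gamma(shape=0.6, rate=10), i.e. about 0.06 counts
    per gene per cell — the per-gene depth of a typical 10x library
    (~1000-2000 UMIs spread over a full transcriptome). 10% of
    gene/group pairs are differentially expressed with log-symmetric
    factors around e^±2 (median ~7-fold), the scale of genuine cell-type
    markers; library sizes vary log-normally by ~20%.
    """

    n_genes: int = 2000
    n_cells: int = 500
    group_proportions: tuple = field(
        default_factory=lambda: ratio_to_proportions(DEFAULT_GROUP_RATIO)
    )
    de_prob: float = 0.1
    de_factor_logmean: float = 2.0
    de_factor_logsd: float = 0.4
    mean_shape: float = 0.6
    mean_rate: float = 10.0
    libsize_logmean: float = 0.0
    libsize_logsd: float = 0.2
    dropout_enabled: bool = False
    dropout_midpoint: float = 0.0
    dropout_shape: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells < 1:
            raise ValueError("n_genes and n_cells must be positive")
        p = np.asarray(self.group_proportions, dtype=float)
        if p.size < 1 or np.any(p <= 0):
            raise ValueError("group_proportions must be positive")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("group_proportions must sum to 1 (use ratio_to_proportions)")
        if not 0.0 <= self.de_prob <= 1.0:
            raise ValueError("de_prob must lie in [0, 1]")
        for name in ("de_factor_logsd", "mean_shape", "mean_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.libsize_logsd < 0:
            raise ValueError("libsize_logsd must be non-negative")


@dataclass
class SimTruth:
    """Ground truth emitted by :func:`simulate_counts`.

    Attributes
    ----------
    cell_group
        1-based group index per cell.
    de_flag
        Per-gene boolean; True iff the gene carries a non-unit factor in
        any group.
    de_factors
        genes x groups matrix of multiplicative mean shifts.
    """

    cell_group: np.ndarray
    de_flag: np.ndarray
    de_factors: np.ndarray


def group_sizes(proportions, n_cells: int) -> np.ndarray:
    """Integer group sizes by largest-remainder rounding; sums to n_cells."""
    p = np.asarray(proportions, dtype=float)
    exact = p * n_cells
    base = np.floor(exact).astype(int)
    short = n_cells - base.sum()
    # distribute the shortfall to the largest fractional parts, ties by index
    order = np.lexsort((np.arange(p.size), -(exact - base)))
    base[order[:short]] += 1
    return base


def simulate_counts(params: SimParams) -> tuple[CountMatrix, SimTruth]:
    """Draw one labeled count matrix from the gamma-Poisson model.

    The cell-gene mean is mu[g, c] = lambda_g * f[g, group(c)] * L_c / mean(L)
    with lambda_g ~ Gamma(mean_shape, mean_rate), L_c ~ LogNormal, and a
    DE factor f that is log-symmetric around 1: with probability de_prob a
    gene/group pair gets factor exp(s * N(de_factor_logmean, de_factor_logsd))
    with a fair random sign s, else factor 1. Counts are Poisson(mu), with
    optional logistic dropout applied afterwards. Identical params (incl.
    seed) give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    n_g, n_c = params.n_genes, params.n_cells
    sizes = group_sizes(params.group_proportions, n_c)
    n_groups = sizes.size
    cell_group = np.repeat(np.arange(1, n_groups + 1), sizes)

    lam = rng.gamma(params.mean_shape, 1.0 / params.mean_rate, size=n_g)

    is_de = rng.random((n_g, n_groups)) < params.de_prob
    log_mag = rng.normal(params.de_factor_logmean, params.de_factor_logsd, (n_g, n_groups))
    sign = np.where(rng.random((n_g, n_groups)) < 0.5, -1.0, 1.0)
    de_factors = np.where(is_de, np.exp(sign * log_mag), 1.0)

    lib = rng.lognormal(params.libsize_logmean, params.libsize_logsd, size=n_c)
    lib_rel = lib / lib.mean()

    mu = lam[:, None] * de_factors[:, cell_group - 1] * lib_rel[None, :]
    counts = rng.poisson(mu).astype(np.int64)

    if params.dropout_enabled:
        p_drop = expit(params.dropout_shape * (params.dropout_midpoint - np.log(mu + 1.0)))
        counts[rng.random((n_g, n_c)) < p_drop] = 0

    gene_ids = np.array([f"gene{i + 1}" for i in range(n_g)], dtype=object)
    cell_ids = np.array([f"cell{i + 1}" for i in range(n_c)], dtype=object)
    truth = SimTruth(
        cell_group=cell_group,
        de_flag=(de_factors != 1.0).any(axis=1),
        de_factors=de_factors,
    )
    return CountMatrix(counts, gene_ids, cell_ids), truth


def write_sim(sim: CountMatrix, truth: SimTruth, directory) -> dict:
    """Write counts and ground truth as the 10x-style text triplet.

    Produces matrix.mtx (coordinate format, genes as rows), genes.tsv,
    barcodes.tsv, labels.tsv (cell_id TAB group) and de_genes.tsv
    (gene_id TAB 0/1). Returns the path of each file written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / fname for name, fname in [
        ("matrix", "matrix.mtx"),
        ("genes", "genes.tsv"),
        ("barcodes", "barcodes.tsv"),
        ("labels", "labels.tsv"),
        ("de_genes", "de_genes.tsv"),
    ]}
    mmwrite(str(paths["matrix"]), sp.coo_matrix(sim.dense()), field="integer")
    paths["genes"].write_text("".join(f"{g}\n" for g in sim.gene_ids))
    paths["barcodes"].write_text("".join(f"{c}\n" for c in sim.cell_ids))
    paths["labels"].write_text(
        "".join(f"{c}\t{g}\n" for c, g in zip(sim.cell_ids, truth.cell_group))
    )
    paths["de_genes"].write_text(
        "".join(f"{g}\t{int(f)}\n" for g, f in zip(sim.gene_ids, truth.de_flag))
    )
    return paths


def params_from_dict(config: dict) -> SimParams:
    """Build SimParams from a flat config dict; 'ratio' overrides proportions."""
    cfg = dict(config)
    ratio = cfg.pop("ratio", None)
    if ratio is not None:
        if isinstance(ratio, str):
            ratio = [float(x) for x in ratio.replace(":", ",").split(",") if x.strip()]
        cfg["group_proportions"] = ratio_to_proportions(ratio)
    valid = {f for f in SimParams.__dataclass_fields__}
    unknown = set(cfg) - valid
    if unknown:
        raise ValueError(f"unknown simulation parameters: {sorted(unknown)}")
    return SimParams(**cfg)


def params_to_dict(params: SimParams) -> dict:
    d = asdict(params)
    d["group_proportions"] = list(d["group_proportions"])
    return d
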
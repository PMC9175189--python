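# ientropy

Intrinsic-entropy feature selection for single-cell RNA-seq.

Clustering and classification of scRNA-seq data depend heavily on which
genes are used as features. `ientropy` scores genes by decomposing each
gene's total expression fluctuation into the part imposed by the rest of
the transcriptome and the part generated by the gene's own dynamics, and
selects genes rich in the latter.

## The model

Let x be a gene's log-normalized expression across cells and Z the
remaining genes, summarised by the top principal components of the
expression matrix. Treating (x, Z) as jointly Gaussian, the total
differential entropy of x splits exactly into mutual information and
conditional entropy:

    TE(x) = H(x) = MI(x, Z) + H(x | Z) = EE(x) + IE(x)

- **TE (total entropy)** — ½ ln(2πe σ²ₓ): the gene's raw fluctuation.
- **EE (extrinsic entropy)** — MI(x, Z) = −½ ln(1 − R²): fluctuation
  shared with the environment, treated as "noise" from the gene's
  viewpoint.
- **IE (intrinsic entropy)** — H(x | Z) = ½ ln(2πe σ²ₓ|Z), with
  σ²ₓ|Z = σ²ₓ − Σ_xZ Σ_Z⁻¹ Σ_Zx the Schur complement (equivalently the
  determinant ratio |Σ_{x,Z}| / |Σ_Z|): the gene's own regulatory
  fluctuation.

High-IE genes are the informative features. The package also provides
PIE, a marker-set statistic (total IE of the top-k markers relative to
the global top-k IE genes, k = 10 by default), a gamma-Poisson
group-structured count simulator, and an ARI clustering benchmark for
comparing feature-selection strategies (IE, TE, variance, random). All
entropies are in nats.

## Worked example

```python
import ientropy as ie

params = ie.SimParams(seed=7)           # 2000 genes, 500 cells, 5 groups
counts, truth = ie.simulate_counts(params)
kept = ie.filter_genes(counts, min_cells=10)
expr = ie.normalize_log(kept)           # ln(1 + 1e4 * count / cell total)
pcs = ie.compute_pcs(expr, n_pcs=20)
table = ie.intrinsic_entropy(expr, pcs)
print(table.head(5).to_string(index=False))

features = ie.select_top(table, k=200)
labels = ie.cluster_cells(expr, features, n_pcs=20, k_clusters=5, seed=0)
truth_labels = ie.ClusterLabels(kept.cell_ids, truth.cell_group, 5)
print("ARI(top-200 IE genes):", round(ie.adjusted_rand_index(labels, truth_labels), 3))
```

prints

```
 gene_id       te       ee       ie  rank  degenerate
gene1883 2.191863 0.137302 2.054561     1       False
gene1340 2.139031 0.097207 2.041824     2       False
 gene185 2.071146 0.060627 2.010518     3       False
 gene411 2.230564 0.232432 1.998132     4       False
  gene70 2.146060 0.149305 1.996755     5       False
ARI(top-200 IE genes): 0.982
```

The table lists each scored gene's total, extrinsic and intrinsic
entropy (nats) with rank by descending IE; TE = IE + EE holds to machine
precision. Clustering the cells on the 200 highest-IE genes recovers the
five simulated groups almost perfectly (adjusted Rand index 0.98,
against ~0.7 for 200 random genes under the same conditions).

The same pipeline is available from the shell:

```sh
ientropy simulate --out sim/ --seed 7
ientropy score --input sim/ --out entropy.tsv --min-genes 0
ientropy select --table entropy.tsv --k 200 --out features.txt
ientropy benchmark --out bench.tsv --seed 7 --replicates 20
```

Inputs may be 10x-style Matrix Market triplets (`matrix.mtx` +
`genes.tsv` + `barcodes.tsv`) or dense CSV/TSV with gene rows. Every
subcommand writes a resolved `*.config.json` next to its outputs and is
byte-identical when rerun with the same seed.

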
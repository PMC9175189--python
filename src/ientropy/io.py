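"""Readers and writers for the supported on-disk layouts.

Two count-matrix layouts are supported, both gene-major:

* 10x-style Matrix Market triplet: a directory (or ``matrix.mtx`` path)
  with ``matrix.mtx``, ``genes.tsv`` and ``barcodes.tsv`` sidecars;
* dense CSV/TSV with gene ids in the first column and a header row of
  cell ids.

Layout is auto-detected from the path; pass ``fmt`` to override.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .containers import CountMatrix

_ENTROPY_COLUMNS = ["gene_id", "te", "ee", "ie", "rank", "degenerate"]


def detect_format(path) -> str:
    path = Path(path)
    if path.is_dir() or path.suffix == ".mtx":
        return "mtx"
    if path.suffix.lower() in (".csv", ".tsv", ".txt"):
        return "dense"
    raise ValueError(
        f"cannot detect layout of {path}: expected a Matrix Market triplet "
        "(directory or .mtx with genes.tsv/barcodes.tsv sidecars) or a dense "
        ".csv/.tsv with gene rows and a cell-id header"
    )


def _read_lines(path: Path) -> np.ndarray:
    # sidecars may be 1-column (ids) or multi-column (10x id + symbol); take col 0
    ids = [line.split("\t")[0] for line in path.read_text().splitlines() if line]
    return np.asarray(ids, dtype=object)


def read_counts(path, fmt: str | None = None) -> CountMatrix:
    """Load a gene x cell count matrix from either supported layout."""
    path = Path(path)
    fmt = fmt or detect_format(path)
    if fmt == "mtx":
        directory = path if path.is_dir() else path.parent
        matrix = path if path.suffix == ".mtx" else directory / "matrix.mtx"
        counts = sp.csr_matrix(mmread(str(matrix)))
        genes = _read_lines(directory / "genes.tsv")
        barcodes = _read_lines(directory / "barcodes.tsv")
        return CountMatrix(counts, genes, barcodes)
    if fmt == "dense":
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        frame = pd.read_csv(path, sep=sep, index_col=0)
        return CountMatrix(
            frame.to_numpy(dtype=np.int64),
            np.asarray(frame.index.astype(str), dtype=object),
            np.asarray(frame.columns.astype(str), dtype=object),
        )
    raise ValueError(f"unknown format {fmt!r}")


def write_counts(m: CountMatrix, path, fmt: str | None = None) -> None:
    """Write counts in the layout mirroring :func:`read_counts`."""
    path = Path(path)
    fmt = fmt or detect_format(path)
    if fmt == "mtx":
        directory = path if path.suffix != ".mtx" else path.parent
        directory.mkdir(parents=True, exist_ok=True)
        mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(m.dense()), field="integer")
        (directory / "genes.tsv").write_text("".join(f"{g}\n" for g in m.gene_ids))
        (directory / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))
        return
    if fmt == "dense":
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        frame = pd.DataFrame(m.dense(), index=m.gene_ids, columns=m.cell_ids)
        frame.to_csv(path, sep=sep)
        return
    raise ValueError(f"unknown format {fmt!r}")


def write_entropy_table(table: pd.DataFrame, path) -> None:
    """Serialize the entropy table as TSV in rank order."""
    out = table[_ENTROPY_COLUMNS].copy()
    out["degenerate"] = out["degenerate"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_entropy_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(_ENTROPY_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"entropy table missing columns: {sorted(missing)}")
    table["degenerate"] = table["degenerate"].astype(bool)
    return table


def write_feature_set(features, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in features))


def read_labels(path) -> pd.DataFrame:
    """Read a labels TSV (cell_id TAB label) with no header."""
    return pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"])
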
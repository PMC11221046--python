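"""Reading and writing the pipeline's tabular inputs and outputs."""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import AdjacencyMatrix, ExpressionMatrix, SimilarityMatrix


def read_expression(
    path,
    genes_in_columns: bool = False,
    nonfinite: str = "drop",
) -> ExpressionMatrix:
    """Read a genes x samples TSV/CSV (first column gene ids, header samples).

    ``genes_in_columns`` accepts the transposed layout.  Rows with
    non-finite values are dropped (default) or rejected per ``nonfinite``.
    """
    path = str(path)
    sep = "," if path.endswith((".csv", ".csv.gz")) else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if genes_in_columns:
        df = df.T
    ge = ExpressionMatrix(
        [str(g) for g in df.index],
        df.to_numpy(dtype=float),
        [str(s) for s in df.columns],
    )
    return ge.drop_nonfinite(policy=nonfinite)


def write_matrix_tsv(
    mat: SimilarityMatrix | AdjacencyMatrix | np.ndarray,
    gene_ids: list[str],
    path,
) -> None:
    """Dump a square gene x gene matrix as (optionally gzipped) TSV."""
    values = getattr(mat, "values", mat)
    df = pd.DataFrame(values, index=gene_ids, columns=gene_ids)
    path = str(path)
    if path.endswith(".gz"):
        with gzip.open(path, "wt") as fh:
            df.to_csv(fh, sep="\t")
    else:
        df.to_csv(path, sep="\t")


def write_labels_tsv(gene_ids, labels, path, column: str = "cluster") -> None:
    pd.DataFrame({"gene_id": list(gene_ids), column: list(labels)}).to_csv(
        path, sep="\t", index=False
    )


def read_labels_tsv(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return {str(g): int(c) for g, c in zip(df.iloc[:, 0], df.iloc[:, 1])}


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))
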
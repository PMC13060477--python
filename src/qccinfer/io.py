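"""Readers and writers for the standard on-disk formats.

Expression matrices are accepted either as a 10x-style Matrix Market
directory (``matrix.mtx`` with genes x cells orientation plus
``features.tsv`` and ``barcodes.tsv``) or as a dense delimited file (cells
x genes, header row of gene identifiers). Gene panels are one identifier
per line. State tables, candidate sets and distributions round-trip as
TSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from anndata import AnnData

from .state import BinaryStateTable, ProbDist


def read_expression(path: str | Path) -> AnnData:
    """Read a count/expression matrix as cells x genes."""
    path = Path(path)
    if path.is_dir():
        m = scipy.io.mmread(str(path / "matrix.mtx"))  # genes x cells
        genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].astype(str)
        cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
        X = np.asarray(scipy.sparse.csr_matrix(m).T.todense(), dtype=float)
        adata = AnnData(X=X)
        adata.var_names = list(genes)
        adata.obs_names = list(cells)
        return adata
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    frame = pd.read_csv(path, sep=sep, index_col=0)
    adata = AnnData(X=frame.to_numpy(dtype=float))
    adata.var_names = list(map(str, frame.columns))
    adata.obs_names = list(map(str, frame.index))
    return adata


def write_mtx_dir(frame: pd.DataFrame, outdir: str | Path) -> None:
    """Write a cells x genes frame as a genes x cells Matrix Market directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = scipy.sparse.csr_matrix(frame.to_numpy().T)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat)
    pd.Series(frame.columns).to_csv(outdir / "features.tsv", sep="\t",
                                    header=False, index=False)
    pd.Series(frame.index).to_csv(outdir / "barcodes.tsv", sep="\t",
                                  header=False, index=False)


def write_dense_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path)


def read_gene_list(path: str | Path) -> list[str]:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    genes = [ln for ln in lines if ln]
    if not genes:
        raise ValueError(f"gene list {path} is empty")
    return genes


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def state_table_to_json(table: BinaryStateTable) -> str:
    return json.dumps({"gene_order": list(table.gene_order),
                       "counts": table.counts,
                       "n_cells": table.n_cells}, indent=2)


def state_table_from_json(text: str) -> BinaryStateTable:
    d = json.loads(text)
    return BinaryStateTable(tuple(d["gene_order"]),
                            {k: int(v) for k, v in d["counts"].items()},
                            int(d["n_cells"]))


def write_state_table_tsv(table: BinaryStateTable, path: str | Path) -> None:
    rows = sorted(table.counts.items())
    pd.DataFrame(rows, columns=["state", "count"]).to_csv(path, sep="\t", index=False)


def write_probdist_tsv(dist: ProbDist, path: str | Path) -> None:
    d = dist.n_genes
    rows = [(format(i, f"0{d}b"), p) for i, p in enumerate(dist.probs)]
    pd.DataFrame(rows, columns=["state", "probability"]).to_csv(
        path, sep="\t", index=False)
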
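"""From count matrices to binarized state tables, amplitudes and targets.

Pipeline: total-count normalize + log1p -> restrict to the selected gene
panel -> binarize (active iff expression > threshold) -> aggregate per-state
cell counts. Mono-culture counts are L2-normalized into baseline amplitudes
alpha_s = C(s)/sqrt(sum C^2); co-culture counts are L2-normalized and squared
into the target probability distribution Q(s).
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import scanpy as sc
from anndata import AnnData

from .state import AmplitudeVector, BinaryStateTable, ProbDist, StateVector

__all__ = [
    "normalize_log1p",
    "binarize",
    "amplitudes_from_counts",
    "target_distribution",
    "tensor_initial_state",
    "BinaryStateTable",
    "AmplitudeVector",
    "ProbDist",
]


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if hasattr(X, "todense") else X, dtype=float)


def normalize_log1p(raw: AnnData, target_sum: float | None = None) -> AnnData:
    """Total-count normalize each cell then apply X' = log(1 + X).

    ``target_sum=None`` scales every cell to the median total count over
    cells (the scanpy default). Cells with zero total count cannot be
    normalized and are rejected with their identifiers.
    """
    X = _dense(raw.X)
    if np.any(X < 0) or not np.all(np.isfinite(X)):
        raise ValueError("raw counts must be finite and non-negative")
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        bad = list(np.asarray(raw.obs_names)[totals == 0])
        raise ValueError(f"all-zero cells cannot be normalized: {bad}")
    adata = AnnData(X=X.copy(), obs=raw.obs.copy(), var=raw.var.copy())
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    return adata


def binarize(adata: AnnData, genes: list[str] | tuple[str, ...] | None = None,
             threshold: float = 0.0) -> BinaryStateTable:
    """Binarize expression (active iff value > threshold) and count states.

    ``genes`` restricts and orders the columns (the gene panel); by default
    all columns are used in their stored order.
    """
    gene_order = tuple(genes) if genes is not None else tuple(adata.var_names)
    if not gene_order:
        raise ValueError("gene selection is empty")
    missing = [g for g in gene_order if g not in adata.var_names]
    if missing:
        raise KeyError(f"selected genes absent from matrix: {missing}")
    X = _dense(adata[:, list(gene_order)].X)
    bits = (X > threshold).astype(np.uint8)
    states = Counter("".join(map(str, row)) for row in bits)
    return BinaryStateTable(gene_order, dict(states), n_cells=bits.shape[0])


def amplitudes_from_counts(table: BinaryStateTable) -> AmplitudeVector:
    """L2-normalize state counts into baseline amplitudes alpha_s."""
    c = table.count_vector()
    return AmplitudeVector(c / np.linalg.norm(c), table.gene_order)


def target_distribution(table: BinaryStateTable) -> ProbDist:
    """Square the L2-normalized counts into the target distribution Q(s).

    Squaring a unit-L2 vector already sums to one; the explicit
    renormalization is a safeguard so Q is a valid probability measure.
    """
    alpha = amplitudes_from_counts(table).amplitudes
    q = alpha ** 2
    return ProbDist(q / q.sum(), table.gene_order)


def tensor_initial_state(psi1: AmplitudeVector, psi2: AmplitudeVector) -> StateVector:
    """Separable joint baseline |Psi> = |psi_CT1> (x) |psi_CT2> (CT1 = high bits)."""
    return StateVector(np.kron(psi1.amplitudes, psi2.amplitudes).astype(complex),
                       n_ct1=psi1.n_genes, n_ct2=psi2.n_genes)
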
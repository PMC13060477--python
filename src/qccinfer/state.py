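"""Shared state containers and basis-index conventions.

A register of d genes maps gene-order position k to qubit k. Bitstrings are
read left to right, and the basis index is big-endian:

    index(s) = sum_k s_k * 2**(d - 1 - k)

so qubit 0 is the most significant bit. The same convention is used for
amplitude vectors, probability vectors and the joint (CT1 ⊗ CT2) register,
where the CT1 qubits occupy the high bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

Register = Literal["CT1", "CT2"]


def index_of_bitstring(s: str) -> int:
    """Big-endian basis index of a bitstring."""
    return int(s, 2) if s else 0


def bitstring_of_index(i: int, d: int) -> str:
    return format(i, f"0{d}b")


@dataclass(frozen=True)
class BinaryStateTable:
    """Per-cell-population histogram of binarized expression states.

    ``counts`` maps each observed bitstring s in {0,1}^d to the number of
    cells C(s) found in that state; d == len(gene_order).
    """

    gene_order: tuple[str, ...]
    counts: dict[str, int]
    n_cells: int

    def __post_init__(self) -> None:
        d = len(self.gene_order)
        if not self.counts:
            raise ValueError("state table has no observed states")
        for s, c in self.counts.items():
            if len(s) != d or set(s) - {"0", "1"}:
                raise ValueError(f"malformed bitstring {s!r} for {d} genes")
            if c <= 0:
                raise ValueError(f"non-positive count for state {s!r}")
        total = sum(self.counts.values())
        if total != self.n_cells:
            raise ValueError(f"counts sum to {total}, expected n_cells={self.n_cells}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_order)

    def count_vector(self) -> np.ndarray:
        """Dense count vector over all 2^d basis states."""
        v = np.zeros(2 ** self.n_genes)
        for s, c in self.counts.items():
            v[index_of_bitstring(s)] = c
        return v


@dataclass(frozen=True)
class AmplitudeVector:
    """Real, L2-normalized amplitudes over the 2^d basis states of one register."""

    amplitudes: np.ndarray
    gene_order: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "amplitudes", a)
        if a.shape != (2 ** len(self.gene_order),):
            raise ValueError("amplitude length must be 2^(number of genes)")
        if np.any(a < 0):
            raise ValueError("amplitudes must be non-negative")
        if abs(a @ a - 1.0) > 1e-12:
            raise ValueError("amplitudes must be L2-normalized")

    @property
    def n_genes(self) -> int:
        return len(self.gene_order)


@dataclass(frozen=True)
class ProbDist:
    """Normalized probability vector over the bitstrings of one register."""

    probs: np.ndarray
    gene_order: tuple[str, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (2 ** len(self.gene_order),):
            raise ValueError("probability length must be 2^(number of genes)")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_order)


@dataclass
class StateVector:
    """Joint statevector over the CT1 (high bits) and CT2 (low bits) registers."""

    amplitudes: np.ndarray
    n_ct1: int
    n_ct2: int

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=complex)
        if a.shape != (2 ** (self.n_ct1 + self.n_ct2),):
            raise ValueError("statevector length must be 2^(n_ct1 + n_ct2)")
        nrm = np.linalg.norm(a)
        if abs(nrm - 1.0) > 1e-10:
            raise ValueError(f"statevector norm {nrm} deviates from 1 beyond 1e-10")
        self.amplitudes = a

    @property
    def n_qubits(self) -> int:
        return self.n_ct1 + self.n_ct2

    def copy(self) -> "StateVector":
        return StateVector(self.amplitudes.copy(), self.n_ct1, self.n_ct2)
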
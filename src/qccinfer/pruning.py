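"""Candidate-gate pruning from the difference of global density matrices.

With real amplitude encodings, both the non-interacting and interacting
global states are real vectors, so Delta rho = |Psi_co><Psi_co| -
|Psi_mo><Psi_mo| is a real symmetric, traceless matrix. A CRX gate moves
amplitude between joint basis states that differ exactly on its target bit
while the control bit is set; the decode rule below inverts that picture:
every off-diagonal element |Delta rho_ij| above the cutoff nominates the
differing bit positions of (i, j) as targets and the positions where both
basis states are 1 as controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .state import StateVector, bitstring_of_index


@dataclass
class DensityDelta:
    """Difference of the interacting and non-interacting pure-state density matrices."""

    delta: np.ndarray
    cutoff: float = 0.01

    def __post_init__(self) -> None:
        d = np.asarray(self.delta, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("delta must be square")
        self.delta = d
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class CandidateSet:
    """Ordered (control, target) qubit pairs, ranked by |Delta rho| provenance."""

    pairs: list[tuple[int, int]] = field(default_factory=list)
    provenance: dict[tuple[int, int], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def to_records(self, gene_map: dict[int, str] | None = None) -> list[dict]:
        recs = []
        for c, t in self.pairs:
            rec = {"control_qubit": c, "target_qubit": t,
                   "max_abs_delta": self.provenance[(c, t)]}
            if gene_map is not None:
                rec["control_gene"] = gene_map[c]
                rec["target_gene"] = gene_map[t]
            recs.append(rec)
        return recs


def density_delta(psi_mo: StateVector, psi_co: StateVector,
                  cutoff: float = 0.01) -> DensityDelta:
    """Delta rho = |Psi_co><Psi_co| - |Psi_mo><Psi_mo| (real amplitudes assumed)."""
    a = psi_mo.amplitudes
    b = psi_co.amplitudes
    if a.shape != b.shape:
        raise ValueError("state dimensions differ")
    ar, br = a.real, b.real
    return DensityDelta(np.outer(br, br) - np.outer(ar, ar), cutoff)


def candidates_from_delta(delta: DensityDelta) -> CandidateSet:
    """Decode above-cutoff off-diagonal elements into (control, target) pairs.

    Pairs internal to one register and cross-register pairs are both kept:
    the circuit models intracellular regulation and intercellular signaling
    alike. The result is deduplicated and ranked by the largest |Delta rho|
    element that nominated each pair.
    """
    m = delta.delta
    dim = m.shape[0]
    d = int(round(np.log2(dim)))
    if 2 ** d != dim:
        raise ValueError("delta dimension is not a power of two")
    best: dict[tuple[int, int], float] = {}
    ii, jj = np.nonzero(np.triu(np.abs(m), k=1) > delta.cutoff)
    for i, j in zip(ii.tolist(), jj.tolist()):
        w = abs(m[i, j])
        si = bitstring_of_index(i, d)
        sj = bitstring_of_index(j, d)
        targets = [k for k in range(d) if si[k] != sj[k]]
        controls = [k for k in range(d) if si[k] == "1" and sj[k] == "1"]
        for c in controls:
            for t in targets:
                if c != t:
                    key = (c, t)
                    if w > best.get(key, 0.0):
                        best[key] = w
    ranked = sorted(best, key=lambda p: (-best[p], p))
    return CandidateSet(pairs=ranked, provenance=best)
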
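"""Statevector simulation of controlled-RX circuits and the marginal-KL cost.

The transformation model is a sequence of CRX gates acting on the joint
CT1 ⊗ CT2 register: RX(theta) is applied to the target qubit whenever the
control qubit is |1>. The training cost is the sum of KL divergences between
the per-register marginals of the simulated output state and the empirical
target distributions of the interacting condition.

Simulation is dense and in-memory, which is exact and fast for the <= ~14
qubit systems this model is designed for (small, curated gene panels). A
different backend may be substituted via the ``simulate_fn`` hook as long as
it honours the big-endian basis convention of :mod:`qccinfer.state`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import rel_entr

from .state import ProbDist, Register, StateVector

DEFAULT_KL_EPS = 1e-10


@dataclass(frozen=True)
class GateSpec:
    """One controlled-RX gate: RX(angle) on ``target`` conditioned on ``control``."""

    control: int
    target: int
    angle: float

    def __post_init__(self) -> None:
        if self.control == self.target:
            raise ValueError("control and target qubits must differ")
        if self.control < 0 or self.target < 0:
            raise ValueError("qubit indices must be non-negative")


@dataclass
class Topology:
    """An ordered CRX gate sequence; order is significant, duplicates allowed."""

    gates: list[GateSpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.gates)

    def __iter__(self):
        return iter(self.gates)

    def with_angles(self, angles: Sequence[float]) -> "Topology":
        if len(angles) != len(self.gates):
            raise ValueError("need one angle per gate")
        return Topology([GateSpec(g.control, g.target, float(a))
                         for g, a in zip(self.gates, angles)])

    def angles(self) -> np.ndarray:
        return np.array([g.angle for g in self.gates])

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            [{"control": g.control, "target": g.target, "angle_rad": g.angle}
             for g in self.gates],
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Topology":
        return cls([GateSpec(int(e["control"]), int(e["target"]), float(e["angle_rad"]))
                    for e in json.loads(text)])

    def to_qasm3(self, n_qubits: int) -> str:
        """OpenQASM 3 rendering of the circuit (qubit k = gene-order position k)."""
        lines = ["OPENQASM 3.0;", 'include "stdgates.inc";', f"qubit[{n_qubits}] q;"]
        for g in self.gates:
            lines.append(f"crx({g.angle!r}) q[{g.control}], q[{g.target}];")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class CostValue:
    """Decomposed training cost: total = kl_ct1 + kl_ct2."""

    total: float
    kl_ct1: float
    kl_ct2: float


def rx_matrix(theta: float) -> np.ndarray:
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    return np.array([[c, -1j * s], [-1j * s, c]])


def apply_crx(state: StateVector, gate: GateSpec) -> StateVector:
    """Apply a single CRX gate; returns a new, norm-preserved statevector."""
    d = state.n_qubits
    if gate.control >= d or gate.target >= d:
        raise ValueError(f"gate {gate} out of range for {d} qubits")
    psi = state.amplitudes.reshape([2] * d).copy()
    sel = [slice(None)] * d
    sel[gate.control] = 1
    sub = psi[tuple(sel)]  # control = |1> block; a copy
    t_ax = gate.target if gate.target < gate.control else gate.target - 1
    sub = np.moveaxis(sub, t_ax, 0)
    shape = sub.shape
    mixed = rx_matrix(gate.angle) @ sub.reshape(2, -1)
    psi[tuple(sel)] = np.moveaxis(mixed.reshape(shape), 0, t_ax)
    return StateVector(psi.reshape(-1), state.n_ct1, state.n_ct2)


def simulate(topology: Topology, initial: StateVector) -> StateVector:
    """Evolve the initial state through the gate sequence, |psi'> = U(tau, theta)|Psi>."""
    out = initial
    for gate in topology:
        out = apply_crx(out, gate)
    return out


def marginal(state: StateVector, register: Register,
             gene_order: tuple[str, ...] | None = None) -> ProbDist:
    """Born-rule marginal over one register (exact, infinite-shot limit)."""
    probs = np.abs(state.amplitudes) ** 2
    joint = probs.reshape(2 ** state.n_ct1, 2 ** state.n_ct2)
    if register == "CT1":
        p = joint.sum(axis=1)
        d = state.n_ct1
    elif register == "CT2":
        p = joint.sum(axis=0)
        d = state.n_ct2
    else:
        raise ValueError(f"unknown register {register!r}")
    p = p / p.sum()
    if gene_order is None:
        gene_order = tuple(f"q{k}" for k in range(d))
    return ProbDist(p, gene_order)


def sample_bitstrings(state: StateVector, n: int, rng: np.random.Generator) -> np.ndarray:
    """Finite-shot counts over the joint basis (multinomial measurement model)."""
    probs = np.abs(state.amplitudes) ** 2
    return rng.multinomial(n, probs / probs.sum())


def kl_divergence(p, q, eps: float = DEFAULT_KL_EPS) -> float:
    """Smoothed KL divergence D(P || Q).

    Both vectors receive additive smoothing ``eps`` and are renormalized
    before the sum, so empirically-zero target states that the circuit
    populates contribute a large but finite penalty.
    """
    p = np.asarray(p.probs if isinstance(p, ProbDist) else p, dtype=float)
    q = np.asarray(q.probs if isinstance(q, ProbDist) else q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"support mismatch: {p.shape} vs {q.shape}")
    ps = (p + eps) / (p.sum() + eps * p.size)
    qs = (q + eps) / (q.sum() + eps * q.size)
    return float(rel_entr(ps, qs).sum())


def cost(topology: Topology, initial: StateVector,
         q_ct1: ProbDist, q_ct2: ProbDist, eps: float = DEFAULT_KL_EPS) -> CostValue:
    """Sum of marginal KL divergences of the simulated output against the targets."""
    if 2 ** initial.n_ct1 != q_ct1.probs.size or 2 ** initial.n_ct2 != q_ct2.probs.size:
        raise ValueError("target distribution sizes inconsistent with register sizes")
    out = simulate(topology, initial)
    kl1 = kl_divergence(marginal(out, "CT1"), q_ct1, eps)
    kl2 = kl_divergence(marginal(out, "CT2"), q_ct2, eps)
    return CostValue(kl1 + kl2, kl1, kl2)
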
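import numpy as np
import pytest
from math import pi

import qccinfer as q


@pytest.fixture
def psi_ct1():
    c = np.array([3.0, 0.0, 0.0, 4.0])
    return q.AmplitudeVector(c / np.linalg.norm(c), ("gA", "gB"))


@pytest.fixture
def psi_ct2():
    c = np.array([4.0, 1.0, 2.0, 2.0])
    return q.AmplitudeVector(c / np.linalg.norm(c), ("gC", "gD"))


@pytest.fixture
def planted_2gate(psi_ct1, psi_ct2):
    """Exact targets generated by CRX(pi/2) on (0->2) then (2->1)."""
    topo = q.Topology([q.GateSpec(0, 2, pi / 2), q.GateSpec(2, 1, pi / 2)])
    initial, q1, q2 = q.generate_planted_circuit(
        q.PlantedCircuitSpec(topo, psi_ct1, psi_ct2))
    return topo, initial, q1, q2


def dense_unitary(gates, n_qubits):
    """Independent oracle: explicit 2^d x 2^d unitary via Kronecker products."""
    dim = 2 ** n_qubits
    U = np.eye(dim, dtype=complex)
    for g in gates:
        P0 = np.array([[1, 0], [0, 0]], dtype=complex)
        P1 = np.array([[0, 0], [0, 1]], dtype=complex)
        c, s = np.cos(g.angle / 2), np.sin(g.angle / 2)
        RX = np.array([[c, -1j * s], [-1j * s, c]])
        term0 = np.eye(1, dtype=complex)
        term1 = np.eye(1, dtype=complex)
        for k in range(n_qubits):
            if k == g.control:
                f0, f1 = P0, P1
            elif k == g.target:
                f0, f1 = np.eye(2, dtype=complex), RX
            else:
                f0 = f1 = np.eye(2, dtype=complex)
            term0 = np.kron(term0, f0)
            term1 = np.kron(term1, f1)
        U = (term0 + term1) @ U
    return U
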
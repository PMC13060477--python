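import numpy as np
import pytest
from math import pi, log

import qccinfer as q
from conftest import dense_unitary


def state(amps, n_ct1, n_ct2):
    a = np.asarray(amps, dtype=complex)
    return q.StateVector(a / np.linalg.norm(a), n_ct1, n_ct2)


def random_state(rng, n_ct1, n_ct2):
    a = rng.normal(size=2 ** (n_ct1 + n_ct2))
    return state(a, n_ct1, n_ct2)


class TestApplyCrx:
    def test_zero_angle_is_identity(self):
        rng = np.random.default_rng(1)
        sv = random_state(rng, 1, 1)
        out = q.apply_crx(sv, q.GateSpec(0, 1, 0.0))
        assert np.allclose(out.amplitudes, sv.amplitudes)

    def test_inert_when_control_is_zero(self):
        sv = state([1, 0, 0, 0], 1, 1)  # |00>
        out = q.apply_crx(sv, q.GateSpec(0, 1, pi / 2))
        assert np.allclose(out.amplitudes, sv.amplitudes)

    def test_full_rotation_flips_target_with_phase(self):
        sv = state([0, 0, 0, 1], 1, 1)  # |11>
        out = q.apply_crx(sv, q.GateSpec(0, 1, pi))
        assert np.allclose(out.amplitudes, [0, 0, -1j, 0])  # -i|10>

    def test_half_rotation_splits_probability(self):
        sv = state([0, 0, 1, 0], 1, 1)  # |10>
        out = q.apply_crx(sv, q.GateSpec(0, 1, pi / 2))
        expected = np.array([0, 0, 1 / np.sqrt(2), -1j / np.sqrt(2)])
        assert np.allclose(out.amplitudes, expected)
        assert np.allclose(np.abs(out.amplitudes) ** 2, [0, 0, 0.5, 0.5])

    def test_control_equals_target_rejected(self):
        with pytest.raises(ValueError):
            q.GateSpec(1, 1, pi)

    def test_out_of_range_qubit_rejected(self):
        sv = state([1, 0, 0, 0], 1, 1)
        with pytest.raises(ValueError):
            q.apply_crx(sv, q.GateSpec(0, 5, pi))


class TestSimulate:
    def test_empty_topology_returns_initial(self):
        rng = np.random.default_rng(2)
        sv = random_state(rng, 2, 1)
        out = q.simulate(q.Topology([]), sv)
        assert np.allclose(out.amplitudes, sv.amplitudes)

    def test_disjoint_gates_commute(self):
        rng = np.random.default_rng(3)
        sv = random_state(rng, 2, 2)
        g1, g2 = q.GateSpec(0, 1, 0.7), q.GateSpec(2, 3, 1.9)
        ab = q.simulate(q.Topology([g1, g2]), sv)
        ba = q.simulate(q.Topology([g2, g1]), sv)
        assert np.allclose(ab.amplitudes, ba.amplitudes, atol=1e-12)

    def test_matches_dense_matrix_oracle(self):
        """Sparse axis-wise application agrees with an explicit Kronecker unitary."""
        rng = np.random.default_rng(4)
        for trial in range(10):
            n1, n2 = int(rng.integers(1, 3)), int(rng.integers(1, 3))
            d = n1 + n2
            sv = random_state(rng, n1, n2)
            gates = []
            for _ in range(int(rng.integers(1, 6))):
                c, t = rng.choice(d, size=2, replace=False)
                gates.append(q.GateSpec(int(c), int(t), float(rng.uniform(-pi, pi))))
            out = q.simulate(q.Topology(gates), sv)
            oracle = dense_unitary(gates, d) @ sv.amplitudes
            assert np.allclose(out.amplitudes, oracle, atol=1e-9)

    def test_norm_preserved_for_random_topologies(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            sv = random_state(rng, 2, 2)
            gates = [q.GateSpec(*rng.choice(4, 2, replace=False).tolist(),
                                float(rng.uniform(-2 * pi, 2 * pi)))
                     for _ in range(8)]
            out = q.simulate(q.Topology(gates), sv)
            assert abs(np.linalg.norm(out.amplitudes) - 1) < 1e-10


class TestMarginal:
    def test_product_state_marginal_is_component_distribution(self, psi_ct1, psi_ct2):
        sv = q.tensor_initial_state(psi_ct1, psi_ct2)
        m1 = q.marginal(sv, "CT1")
        m2 = q.marginal(sv, "CT2")
        assert np.allclose(m1.probs, psi_ct1.amplitudes ** 2, atol=1e-12)
        assert np.allclose(m2.probs, psi_ct2.amplitudes ** 2, atol=1e-12)

    def test_bell_state_has_uniform_marginals(self):
        sv = state([1, 0, 0, 1], 1, 1)
        assert np.allclose(q.marginal(sv, "CT1").probs, [0.5, 0.5])
        assert np.allclose(q.marginal(sv, "CT2").probs, [0.5, 0.5])

    def test_marginals_sum_to_one(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            sv = random_state(rng, 2, 3)
            for reg in ("CT1", "CT2"):
                assert q.marginal(sv, reg).probs.sum() == pytest.approx(1, abs=1e-12)

    def test_unknown_register_rejected(self):
        sv = state([1, 0, 0, 0], 1, 1)
        with pytest.raises(ValueError):
            q.marginal(sv, "CT3")


class TestKlDivergence:
    def test_zero_iff_equal(self):
        p = np.array([0.2, 0.3, 0.5])
        assert q.kl_divergence(p, p) == pytest.approx(0, abs=1e-9)
        assert q.kl_divergence(p, np.array([0.5, 0.3, 0.2])) > 0

    def test_point_mass_vs_uniform_is_log2(self):
        d = q.kl_divergence(np.array([1.0, 0.0]), np.array([0.5, 0.5]), eps=1e-15)
        assert d == pytest.approx(log(2), rel=1e-6)

    def test_smoothing_keeps_zero_support_finite(self):
        eps = 1e-10
        p = np.array([0.5, 0.5])
        qq = np.array([1.0, 0.0])
        got = q.kl_divergence(p, qq, eps=eps)
        # independent evaluation of the smoothed formula
        ps = (p + eps) / (p + eps).sum()
        qs = (qq + eps) / (qq + eps).sum()
        expected = float((ps * np.log(ps / qs)).sum())
        assert np.isfinite(got)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            q.kl_divergence(np.array([1.0]), np.array([0.5, 0.5]))


class TestCost:
    def test_zero_when_targets_equal_baseline_marginals(self, psi_ct1, psi_ct2):
        sv = q.tensor_initial_state(psi_ct1, psi_ct2)
        q1 = q.ProbDist(psi_ct1.amplitudes ** 2, psi_ct1.gene_order)
        q2 = q.ProbDist(psi_ct2.amplitudes ** 2, psi_ct2.gene_order)
        cv = q.cost(q.Topology([]), sv, q1, q2)
        assert cv.total == pytest.approx(0, abs=1e-7)

    def test_empty_topology_cost_is_sum_of_baseline_kls(self, planted_2gate):
        _, initial, q1, q2 = planted_2gate
        cv = q.cost(q.Topology([]), initial, q1, q2)
        k1 = q.kl_divergence(q.marginal(initial, "CT1"), q1)
        k2 = q.kl_divergence(q.marginal(initial, "CT2"), q2)
        assert cv.total == pytest.approx(k1 + k2, abs=1e-12)
        assert cv.total == pytest.approx(cv.kl_ct1 + cv.kl_ct2, abs=1e-12)
        assert cv.total > 0

    def test_invariant_under_appending_zero_angle_gates(self, planted_2gate):
        topo, initial, q1, q2 = planted_2gate
        base = q.cost(topo, initial, q1, q2).total
        padded = q.Topology(list(topo.gates) + [q.GateSpec(1, 3, 0.0),
                                                q.GateSpec(3, 0, 0.0)])
        assert q.cost(padded, initial, q1, q2).total == pytest.approx(base, abs=1e-12)


class TestTopologySerialization:
    def test_json_roundtrip(self):
        topo = q.Topology([q.GateSpec(0, 2, pi / 2), q.GateSpec(2, 1, 1.345)])
        back = q.Topology.from_json(topo.to_json())
        assert back.gates == topo.gates

    def test_qasm3_lists_gates_in_order(self):
        topo = q.Topology([q.GateSpec(0, 2, pi / 2), q.GateSpec(2, 1, 1.0)])
        text = topo.to_qasm3(4)
        assert "OPENQASM 3.0;" in text
        i0 = text.index("q[0], q[2]")
        i1 = text.index("q[2], q[1]")
        assert i0 < i1
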
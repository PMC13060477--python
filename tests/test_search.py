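import itertools

import numpy as np
import pytest
from math import pi

import qccinfer as q
from qccinfer.search import CostEvaluator, _occam_prune


def candidate_set(pairs):
    return q.CandidateSet(pairs=list(pairs), provenance={p: 1.0 for p in pairs})


def planted_instance(gates, psi1, psi2):
    topo = q.Topology([q.GateSpec(c, t, pi / 2) for c, t in gates])
    initial, q1, q2 = q.generate_planted_circuit(
        q.PlantedCircuitSpec(topo, psi1, psi2))
    return initial, q1, q2


@pytest.fixture
def all_pairs_2x2():
    return [(i, j) for i in range(4) for j in range(4) if i != j]


ALGORITHMS = [q.nwise_local_search, q.multi_epoch_search, q.qubo_select_and_order]


class TestCommonBehaviour:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_perfect_baseline_returns_empty_topology(self, algorithm, psi_ct1, psi_ct2):
        initial = q.tensor_initial_state(psi_ct1, psi_ct2)
        q1 = q.ProbDist(psi_ct1.amplitudes ** 2, psi_ct1.gene_order)
        q2 = q.ProbDist(psi_ct2.amplitudes ** 2, psi_ct2.gene_order)
        res = algorithm(candidate_set([(0, 2), (2, 1)]), initial, q1, q2,
                        q.SearchConfig(seed=0, epochs=3))
        assert len(res.topology) == 0
        assert res.kl_final == pytest.approx(res.kl_initial)

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_empty_candidate_set_returns_baseline(self, algorithm, planted_2gate):
        _, initial, q1, q2 = planted_2gate
        res = algorithm(candidate_set([]), initial, q1, q2, q.SearchConfig(seed=0))
        assert len(res.topology) == 0
        assert res.kl_final == pytest.approx(res.kl_initial)

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_never_worse_than_baseline(self, algorithm, psi_ct1, psi_ct2,
                                       all_pairs_2x2):
        rng = np.random.default_rng(11)
        counts = rng.integers(1, 30, size=4).astype(float)
        targets_tbl = q.BinaryStateTable(
            ("x", "y"), {format(i, "02b"): int(c) for i, c in enumerate(counts)},
            int(counts.sum()))
        q1 = q.target_distribution(targets_tbl)
        q2 = q.ProbDist(psi_ct2.amplitudes ** 2, psi_ct2.gene_order)
        initial = q.tensor_initial_state(psi_ct1, psi_ct2)
        cfg = q.SearchConfig(seed=2, epochs=5, max_gates=4)
        res = algorithm(candidate_set(all_pairs_2x2[:6]), initial, q1, q2, cfg)
        assert res.kl_final <= res.kl_initial + cfg.improvement_tol

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_seeded_determinism(self, algorithm, planted_2gate):
        _, initial, q1, q2 = planted_2gate
        cands = candidate_set([(0, 2), (2, 1), (1, 3), (3, 0)])
        cfg = q.SearchConfig(seed=42, epochs=5)
        r1 = algorithm(cands, initial, q1, q2, cfg)
        r2 = algorithm(cands, initial, q1, q2, cfg)
        assert r1.to_json() == r2.to_json()

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_planted_two_gate_circuit_recovered(self, algorithm, planted_2gate):
        """Order-sensitive planted transformation is matched to ~zero cost."""
        _, initial, q1, q2 = planted_2gate
        cands = candidate_set([(0, 2), (2, 1), (1, 3), (3, 0), (0, 1)])
        res = algorithm(cands, initial, q1, q2, q.SearchConfig(seed=1, epochs=10))
        assert res.kl_final < 1e-6

    def test_trace_costs_non_increasing_at_accepted_moves(self, planted_2gate):
        _, initial, q1, q2 = planted_2gate
        cands = candidate_set([(0, 2), (2, 1), (1, 3)])
        res = q.nwise_local_search(cands, initial, q1, q2, q.SearchConfig(seed=0))
        costs = [t["cost"] for t in res.trace]
        assert all(b <= a + 1e-12 for a, b in zip(costs, costs[1:]))


class TestNwiseAgainstExhaustiveOracle:
    def test_matches_bruteforce_on_toy_systems(self):
        """Greedy local search reaches the enumerated optimum over ordered
        subsets of up to 2 gates on 3-qubit instances."""
        rng = np.random.default_rng(7)
        hits = 0
        for trial in range(5):
            c1 = rng.integers(1, 10, size=2).astype(float)
            c2 = rng.integers(1, 10, size=4).astype(float)
            psi1 = q.AmplitudeVector(c1 / np.linalg.norm(c1), ("a",))
            psi2 = q.AmplitudeVector(c2 / np.linalg.norm(c2), ("b", "c"))
            initial = q.tensor_initial_state(psi1, psi2)
            pool = [(0, 1), (0, 2), (1, 2), (2, 0)]
            planted = [pool[i] for i in rng.choice(4, 2, replace=True)]
            _, q1, q2 = planted_instance(planted, psi1, psi2)
            ev = CostEvaluator(initial, q1, q2)
            oracle = min(ev(perm)
                         for k in range(3)
                         for sub in itertools.combinations(pool, k)
                         for perm in itertools.permutations(sub))
            res = q.nwise_local_search(candidate_set(pool), initial, q1, q2,
                                       q.SearchConfig(seed=trial, max_gates=2))
            if res.kl_final <= oracle + 1e-9:
                hits += 1
        assert hits >= 4


class TestOccamPruning:
    def test_redundant_gate_removed_at_zero_tolerance(self, planted_2gate):
        _, initial, q1, q2 = planted_2gate
        ev = CostEvaluator(initial, q1, q2)
        # (1, 3) twice composes to CRX(pi) on a pair irrelevant to the target
        # shift; dropping the duplicate pair never hurts
        seq = ((0, 2), (2, 1), (1, 3), (1, 3))
        base_cost = ev(((0, 2), (2, 1)))
        pruned, cost = _occam_prune(seq, ev, occam_tol=0.0, trace=[])
        assert cost <= base_cost + 1e-12
        assert len(pruned) <= 2


class TestQubo:
    def test_selects_beneficial_over_harmful_gate(self, psi_ct1, psi_ct2):
        initial, q1, q2 = (lambda t: (t[0], t[1], t[2]))(
            planted_instance([(0, 2)], psi_ct1, psi_ct2))
        res = q.qubo_select_and_order(candidate_set([(0, 2), (1, 3)]),
                                      initial, q1, q2, q.SearchConfig(seed=0))
        assert [(g.control, g.target) for g in res.topology] == [(0, 2)]

    def test_two_selected_gates_are_ordered_by_cost(self, planted_2gate):
        _, initial, q1, q2 = planted_2gate
        res = q.qubo_select_and_order(candidate_set([(2, 1), (0, 2)]),
                                      initial, q1, q2, q.SearchConfig(seed=0))
        # only (0,2) before (2,1) reaches zero cost
        assert [(g.control, g.target) for g in res.topology] == [(0, 2), (2, 1)]
        assert res.kl_final < 1e-9

    def test_anneal_backend_matches_exact_enumeration(self, planted_2gate):
        _, initial, q1, q2 = planted_2gate
        cands = candidate_set([(0, 2), (2, 1), (1, 3), (3, 0), (0, 1), (1, 0)])
        exact = q.qubo_select_and_order(cands, initial, q1, q2,
                                        q.SearchConfig(seed=3, qubo_backend="exact"))
        anneal = q.qubo_select_and_order(cands, initial, q1, q2,
                                         q.SearchConfig(seed=3, qubo_backend="anneal"))
        sel_e = sorted((g.control, g.target) for g in exact.topology)
        sel_a = sorted((g.control, g.target) for g in anneal.topology)
        assert sel_e == sel_a

    def test_unknown_backend_rejected(self, planted_2gate):
        _, initial, q1, q2 = planted_2gate
        with pytest.raises(ValueError):
            q.qubo_select_and_order(candidate_set([(0, 2)]), initial, q1, q2,
                                    q.SearchConfig(qubo_backend="quantum"))
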
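"""Discrete topology search: choose and order CRX(pi/2) gates from a candidate set.

Three interchangeable strategies minimize the marginal-KL cost over ordered
gate sequences drawn from the pruned candidate pairs:

* ``nwise_local_search`` — greedy best-improvement local search over
  insertion and deletion moves, considering compound moves that touch up to
  ``n`` gates per iteration. The most thorough and the most expensive.
* ``multi_epoch_search`` — stochastic forward construction from several
  shuffled starting orders, followed by Occam (parsimony) pruning of gates
  whose removal does not meaningfully worsen the cost. The default.
* ``qubo_select_and_order`` — two-stage: gate *selection* as a quadratic
  binary optimization over per-gate and pairwise cost effects, solved by
  exact enumeration or seeded simulated annealing; then gate *ordering* by
  exhaustive permutation of the selected set (tractable for k <= 8).

All searches hold every angle fixed at pi/2 (partial entanglement) and are
deterministic given the configured seed.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from math import pi

import numpy as np

from .pruning import CandidateSet
from .quantum_core import Topology, GateSpec, cost
from .state import ProbDist, StateVector

GateKey = tuple[int, int]
SeqKey = tuple[GateKey, ...]


@dataclass
class SearchConfig:
    algorithm: str = "multi_epoch"  # nwise_local | multi_epoch | qubo
    n: int = 2
    epochs: int = 20
    max_gates: int = 10
    seed: int = 0
    improvement_tol: float = 1e-6
    occam_tol: float = 1e-4
    qubo_backend: str = "exact"  # exact | anneal
    cardinality_penalty: float | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.n < 1:
            raise ValueError("epochs and n must be >= 1")
        if self.improvement_tol < 0 or self.occam_tol < 0:
            raise ValueError("tolerances must be >= 0")


@dataclass
class SearchResult:
    topology: Topology
    kl_initial: float
    kl_final: float
    trace: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "topology": [{"control": g.control, "target": g.target,
                          "angle_rad": g.angle} for g in self.topology],
            "kl_initial": self.kl_initial,
            "kl_final": self.kl_final,
            "trace": self.trace,
        }, indent=2)


class CostEvaluator:
    """Memoized cost of fixed-angle gate sequences (sequence -> total KL)."""

    def __init__(self, initial: StateVector, q_ct1: ProbDist, q_ct2: ProbDist,
                 angle: float = pi / 2):
        self.initial = initial
        self.q_ct1 = q_ct1
        self.q_ct2 = q_ct2
        self.angle = angle
        self._cache: dict[SeqKey, float] = {}
        self.n_evals = 0

    def topology(self, seq: SeqKey) -> Topology:
        return Topology([GateSpec(c, t, self.angle) for c, t in seq])

    def __call__(self, seq: SeqKey) -> float:
        seq = tuple(seq)
        if seq not in self._cache:
            self._cache[seq] = cost(self.topology(seq), self.initial,
                                    self.q_ct1, self.q_ct2).total
            self.n_evals += 1
        return self._cache[seq]


# ---------------------------------------------------------------------------
# Algorithm 1: n-wise greedy local search


def _elementary_moves(seq: SeqKey, pairs: list[GateKey], max_gates: int):
    if len(seq) < max_gates:
        for pos in range(len(seq) + 1):
            for pair in pairs:
                yield ("insert", pos, pair)
    for idx in range(len(seq)):
        yield ("delete", idx, None)


def _apply_move(seq: SeqKey, move) -> SeqKey:
    kind, pos, pair = move
    if kind == "insert":
        return seq[:pos] + (pair,) + seq[pos:]
    return seq[:pos] + seq[pos + 1:]


def _compound_neighbors(seq: SeqKey, pairs: list[GateKey], max_gates: int,
                        n: int) -> list[SeqKey]:
    """All sequences reachable by up to n elementary moves, first-found order."""
    seen: set[SeqKey] = {seq}
    order: list[SeqKey] = []

    def rec(cur: SeqKey, depth: int) -> None:
        for move in _elementary_moves(cur, pairs, max_gates):
            nxt = _apply_move(cur, move)
            if nxt not in seen:
                seen.add(nxt)
                order.append(nxt)
            if depth + 1 < n:
                rec(nxt, depth + 1)

    rec(seq, 0)
    return order


def nwise_local_search(candidates: CandidateSet, initial: StateVector,
                       q_ct1: ProbDist, q_ct2: ProbDist,
                       cfg: SearchConfig | None = None) -> SearchResult:
    """Greedy best-improvement search over compound insertion/deletion moves.

    Each iteration enumerates every sequence reachable by touching up to
    ``cfg.n`` gates (append or insert a candidate at any position, delete an
    existing gate) and applies the single best cost-reducing one; the search
    stops when no compound move improves the cost by more than
    ``improvement_tol``.
    """
    cfg = cfg or SearchConfig(algorithm="nwise_local")
    ev = CostEvaluator(initial, q_ct1, q_ct2)
    pairs = list(candidates)
    cur: SeqKey = ()
    cur_cost = ev(cur)
    trace = [{"iteration": 0, "cost": cur_cost, "move": "baseline"}]
    it = 0
    while True:
        it += 1
        # lazy deepening: compound (up to n-gate) moves are only enumerated
        # once no single move improves, which preserves the escape power of
        # the n-wise neighborhood at a fraction of its cost
        best_seq, best_cost = None, cur_cost
        for depth in range(1, cfg.n + 1):
            for cand in _compound_neighbors(cur, pairs, cfg.max_gates, depth):
                c = ev(cand)
                if c < best_cost - 1e-15:
                    best_seq, best_cost = cand, c
            if best_seq is not None and cur_cost - best_cost > cfg.improvement_tol:
                break
        if best_seq is None or cur_cost - best_cost <= cfg.improvement_tol:
            break
        cur, cur_cost = best_seq, best_cost
        trace.append({"iteration": it, "cost": cur_cost,
                      "move": f"accept {list(cur)}"})
    return SearchResult(ev.topology(cur), trace[0]["cost"], cur_cost, trace)


# ---------------------------------------------------------------------------
# Algorithm 2: multi-epoch sequential construction + Occam pruning


def _occam_prune(seq: SeqKey, ev: CostEvaluator, occam_tol: float,
                 trace: list[dict]) -> tuple[SeqKey, float]:
    """Repeatedly drop the gate whose removal best keeps (or lowers) the cost."""
    cur = seq
    cur_cost = ev(cur)
    while cur:
        options = [(ev(cur[:i] + cur[i + 1:]), i) for i in range(len(cur))]
        best_cost, best_i = min(options)  # ties -> earliest gate
        if best_cost <= cur_cost + occam_tol:
            cur = cur[:best_i] + cur[best_i + 1:]
            trace.append({"iteration": len(trace), "cost": best_cost,
                          "move": f"occam-drop index {best_i}"})
            cur_cost = best_cost
        else:
            break
    return cur, cur_cost


def multi_epoch_search(candidates: CandidateSet, initial: StateVector,
                       q_ct1: ProbDist, q_ct2: ProbDist,
                       cfg: SearchConfig | None = None) -> SearchResult:
    """Stochastic greedy forward construction with Occam parsimony pruning.

    Each epoch is a stochastic restart of a greedy forward construction:
    the candidate order is reshuffled (seeded), the first gate of the
    sequence is the first candidate in that order (the epoch's random
    starting point), and construction then repeatedly appends the remaining
    candidate with the lowest resulting cost — even when that step does not
    itself improve the cost, since an enabling gate can pay off only after
    later gates — until ``max_gates`` gates are placed. The best prefix of
    each construction is the epoch's result; varying the starting gate
    across epochs is what recovers order-sensitive sequences that a single
    greedy pass misses. The best sequence across epochs is finally pruned
    by the parsimony criterion: any gate whose removal worsens the cost by
    at most ``occam_tol`` is dropped, preferring removals that reduce the
    cost.
    """
    cfg = cfg or SearchConfig(algorithm="multi_epoch")
    ev = CostEvaluator(initial, q_ct1, q_ct2)
    rng = np.random.default_rng(cfg.seed)
    pairs = list(candidates)
    baseline = ev(())
    trace = [{"iteration": 0, "cost": baseline, "move": "baseline"}]
    best_seq: SeqKey = ()
    best_cost = baseline
    for epoch in range(cfg.epochs if pairs else 0):
        order = [pairs[i] for i in rng.permutation(len(pairs))]
        seq: SeqKey = (order[0],)  # stochastic starting gate
        seq_cost = ev(seq)
        prefix_seq, prefix_cost = (seq, seq_cost) if seq_cost < baseline else ((), baseline)
        while len(seq) < cfg.max_gates:
            # candidates may be reused: duplicate CRX(pi/2) gates compose to
            # larger effective rotations, which topologies explicitly allow
            step = [(ev(seq + (g,)), i) for i, g in enumerate(order)]
            step_cost, step_i = min(step)  # ties -> earliest in shuffled order
            seq = seq + (order[step_i],)
            seq_cost = step_cost
            if seq_cost < prefix_cost - cfg.improvement_tol:
                prefix_seq, prefix_cost = seq, seq_cost
        trace.append({"iteration": epoch + 1, "cost": prefix_cost,
                      "move": f"epoch {epoch} built {list(prefix_seq)}"})
        if prefix_cost < best_cost - 1e-15:
            best_seq, best_cost = prefix_seq, prefix_cost
    best_seq, best_cost = _occam_prune(best_seq, ev, cfg.occam_tol, trace)
    return SearchResult(ev.topology(best_seq), baseline, best_cost, trace)


# ---------------------------------------------------------------------------
# Algorithm 3: QUBO selection + exhaustive ordering


def _qubo_energies(a: np.ndarray, b: np.ndarray, X: np.ndarray) -> np.ndarray:
    return X @ a + np.einsum("ki,ij,kj->k", X, np.triu(b, 1), X)


def _solve_qubo_exact(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    m = a.size
    if m > 20:
        raise ValueError("exact QUBO enumeration limited to 20 variables; "
                         "use the 'anneal' backend")
    X = ((np.arange(2 ** m)[:, None] >> np.arange(m)[None, :]) & 1).astype(float)
    e = _qubo_energies(a, b, X)
    return X[int(np.argmin(e))].astype(bool)


def _solve_qubo_anneal(a: np.ndarray, b: np.ndarray, seed: int,
                       sweeps: int = 400, restarts: int = 8) -> np.ndarray:
    """Single-flip Metropolis annealing with geometric cooling (seeded)."""
    m = a.size
    rng = np.random.default_rng(seed)
    B = np.triu(b, 1) + np.triu(b, 1).T
    scale = max(np.abs(a).max(initial=0.0), np.abs(B).max(initial=0.0), 1e-12)
    best_x, best_e = np.zeros(m, bool), 0.0
    for _ in range(restarts):
        x = rng.random(m) < 0.5
        e = float(a @ x + 0.5 * x @ B @ x)
        t = 2.0 * scale
        for sweep in range(sweeps):
            for i in rng.permutation(m):
                de = (1 - 2 * x[i]) * (a[i] + B[i] @ x)
                if de <= 0 or rng.random() < np.exp(-de / t):
                    x[i] = ~x[i]
                    e += de
            t *= 0.98
        if e < best_e:
            best_x, best_e = x.copy(), e
    return best_x


def qubo_select_and_order(candidates: CandidateSet, initial: StateVector,
                          q_ct1: ProbDist, q_ct2: ProbDist,
                          cfg: SearchConfig | None = None) -> SearchResult:
    """Decoupled gate selection (QUBO) and gate ordering (permutation) search.

    Selection minimizes the quadratic surrogate built from simulated cost
    effects: linear terms a_g = L({g}) - L(0) and pairwise terms
    b_gh = L({g,h}) - L({g}) - L({h}) + L(0) with the pair evaluated in
    candidate-rank order. An optional cardinality penalty
    ``lambda * (sum x - max_gates)^2`` discourages oversized selections.
    The selected set is then ordered exhaustively (all k! permutations,
    k <= 8); ties keep candidate-rank order.
    """
    cfg = cfg or SearchConfig(algorithm="qubo")
    ev = CostEvaluator(initial, q_ct1, q_ct2)
    pairs = list(candidates)
    m = len(pairs)
    if m > 30:
        warnings.warn(f"candidate set of {m} gates: the QUBO matrix becomes "
                      "intractable above ~30; consider a stricter pruning cutoff")
    baseline = ev(())
    trace = [{"iteration": 0, "cost": baseline, "move": "baseline"}]
    a = np.array([ev((g,)) - baseline for g in pairs])
    b = np.zeros((m, m))
    for i, j in itertools.combinations(range(m), 2):
        b[i, j] = ev((pairs[i], pairs[j])) - ev((pairs[i],)) - ev((pairs[j],)) + baseline
    aq, bq = a.copy(), b.copy()
    if cfg.cardinality_penalty:
        lam, k = cfg.cardinality_penalty, cfg.max_gates
        aq += lam * (1 - 2 * k)
        bq[np.triu_indices(m, 1)] += 2 * lam
    if cfg.qubo_backend == "exact":
        x = _solve_qubo_exact(aq, bq)
    elif cfg.qubo_backend == "anneal":
        x = _solve_qubo_anneal(aq, bq, cfg.seed)
    else:
        raise ValueError(f"unknown QUBO backend {cfg.qubo_backend!r}")
    selected = [pairs[i] for i in range(m) if x[i]]  # candidate-rank order
    trace.append({"iteration": 1, "cost": float("nan"),
                  "move": f"selected {selected}"})
    k = len(selected)
    if k > 8:
        raise RuntimeError(
            f"{k} gates selected: exhaustive ordering is unreliable beyond 8; "
            "use the n-wise or multi-epoch search instead")
    best_seq: SeqKey = ()
    best_cost = baseline
    for perm in itertools.permutations(selected):
        c = ev(perm)
        if c < best_cost - 1e-15:
            best_seq, best_cost = perm, c
    trace.append({"iteration": 2, "cost": best_cost,
                  "move": f"ordered {list(best_seq)}"})
    return SearchResult(ev.topology(best_seq), baseline, best_cost, trace)


_ALGORITHMS = {
    "nwise_local": nwise_local_search,
    "multi_epoch": multi_epoch_search,
    "qubo": qubo_select_and_order,
}


def search_topology(candidates: CandidateSet, initial: StateVector,
                    q_ct1: ProbDist, q_ct2: ProbDist,
                    cfg: SearchConfig | None = None) -> SearchResult:
    """Dispatch to the configured search algorithm (default: multi-epoch)."""
    cfg = cfg or SearchConfig()
    try:
        fn = _ALGORITHMS[cfg.algorithm]
    except KeyError:
        raise ValueError(f"unknown search algorithm {cfg.algorithm!r}") from None
    return fn(candidates, initial, q_ct1, q_ct2, cfg)
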
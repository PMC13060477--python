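"""Ground-truth synthetic data: rule-based co-culture sampler and planted circuits.

Two generators back the test- and benchmark-suite:

* ``generate_rule_based`` emulates a two-cell-type co-culture experiment
  with explicit regulatory ground truth. In the non-interacting (mono)
  condition every gene is an independent Bernoulli switch. In the
  interacting (co) condition cells of the two types are paired at random
  and directed rules — intercellular ligand-receptor edges conditioning on
  the paired partner's gene, and intracellular cascade edges within a cell
  — resample each target gene conditional on its source's state. Feedback
  cycles are resolved by sweeping the rule list twice.

* ``generate_planted_circuit`` produces targets whose ground truth IS a
  known CRX circuit applied to a known baseline, either as exact Born
  marginals (zero sampling noise) or as seeded finite-cell draws. This
  gives every pipeline stage an instance with a recoverable answer.

The default ground-truth benchmark uses a 2-gene CT1 panel {g50, g90} and a
4-gene CT2 panel {g60, g70, g71, g80}: a ligand-receptor edge g50 -> g60, an
intracellular CT2 cascade g60 -> g70 -> g71 -> g80, return edges g60/g80 ->
g90, and feedback from g80 and g90 back onto the driver g50.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantum_core import Topology, simulate, marginal
from .state import AmplitudeVector, BinaryStateTable, ProbDist, StateVector, bitstring_of_index
from .encoding import tensor_initial_state

N_HOUSEKEEPING = 3  # always-on background genes so every cell has nonzero depth


@dataclass(frozen=True)
class Rule:
    """Directed regulatory edge: target activation probability conditioned on source."""

    source: str
    target: str
    kind: str  # intercellular | intracellular
    p_on_given_src_on: float
    p_on_given_src_off: float

    def __post_init__(self) -> None:
        for p in (self.p_on_given_src_on, self.p_on_given_src_off):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"rule probability {p} outside [0, 1]")
        if self.kind not in ("intercellular", "intracellular"):
            raise ValueError(f"unknown rule kind {self.kind!r}")


@dataclass
class GroundTruthSpec:
    ct1_genes: tuple[str, ...]
    ct2_genes: tuple[str, ...]
    baseline_on_prob: dict[str, float]
    rules: list[Rule]
    n_cells: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        genes = set(self.ct1_genes) | set(self.ct2_genes)
        if len(self.ct1_genes) + len(self.ct2_genes) != len(genes):
            raise ValueError("gene lists overlap")
        for g, p in self.baseline_on_prob.items():
            if g not in genes:
                raise ValueError(f"baseline probability for unknown gene {g!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"baseline probability {p} outside [0, 1]")
        for r in self.rules:
            if r.source not in genes or r.target not in genes:
                raise ValueError(f"rule {r.source}->{r.target} names unknown genes")


@dataclass
class PlantedCircuitSpec:
    topology: Topology
    psi_ct1: AmplitudeVector
    psi_ct2: AmplitudeVector
    exact: bool = True
    n_cells: int = 0
    seed: int = 0


@dataclass
class SyntheticDataset:
    """Binary matrices (cells x genes) and state tables for 2 types x 2 conditions."""

    spec: GroundTruthSpec
    binary: dict[tuple[str, str], pd.DataFrame]  # (cell_type, condition) -> 0/1 frame
    tables: dict[tuple[str, str], BinaryStateTable]

    def count_matrix(self, cell_type: str, condition: str,
                     rng: np.random.Generator) -> pd.DataFrame:
        """Integer count matrix: active genes get lognormal-magnitude counts,
        plus always-on housekeeping columns so no cell has zero total count."""
        b = self.binary[(cell_type, condition)]
        mags = np.ceil(rng.lognormal(mean=1.5, sigma=0.5, size=b.shape)).astype(int)
        counts = b.to_numpy() * mags
        hk = rng.poisson(20, size=(b.shape[0], N_HOUSEKEEPING)) + 1
        cols = list(b.columns) + [f"hk{i}" for i in range(N_HOUSEKEEPING)]
        return pd.DataFrame(np.hstack([counts, hk]), index=b.index, columns=cols)


def default_ground_truth_spec(n_cells: int = 5000, seed: int = 0) -> GroundTruthSpec:
    """The packaged two-cell-type benchmark (2 + 4 genes, 6 qubits)."""
    ct1 = ("g50", "g90")
    ct2 = ("g60", "g70", "g71", "g80")
    baseline = {"g50": 0.5, "g90": 0.3, "g60": 0.3, "g70": 0.3, "g71": 0.3, "g80": 0.3}
    rules = [
        Rule("g50", "g60", "intercellular", 0.9, 0.1),   # ligand-receptor
        Rule("g60", "g70", "intracellular", 0.9, 0.1),   # CT2 cascade
        Rule("g70", "g71", "intracellular", 0.9, 0.1),
        Rule("g71", "g80", "intracellular", 0.9, 0.1),
        Rule("g60", "g90", "intercellular", 0.85, 0.15),  # return arc to CT1 target
        Rule("g80", "g90", "intercellular", 0.85, 0.15),
        Rule("g80", "g50", "intercellular", 0.8, 0.2),    # feedback onto the driver
        Rule("g90", "g50", "intracellular", 0.8, 0.2),
    ]
    return GroundTruthSpec(ct1, ct2, baseline, rules, n_cells=n_cells, seed=seed)


def _table_from_binary(frame: pd.DataFrame) -> BinaryStateTable:
    states = Counter("".join(map(str, row)) for row in frame.to_numpy())
    return BinaryStateTable(tuple(frame.columns), dict(states), n_cells=len(frame))


def generate_rule_based(spec: GroundTruthSpec) -> SyntheticDataset:
    """Sample mono and co conditions for both cell types under the rule set."""
    rng = np.random.default_rng(spec.seed)
    genes = {"CT1": list(spec.ct1_genes), "CT2": list(spec.ct2_genes)}
    register_of = {g: ct for ct, gs in genes.items() for g in gs}
    p0 = np.array([spec.baseline_on_prob.get(g, 0.5)
                   for g in spec.ct1_genes + spec.ct2_genes])
    all_genes = list(spec.ct1_genes) + list(spec.ct2_genes)
    n = spec.n_cells

    # mono: independent Bernoulli switches, separate draws per cell type
    mono = {ct: (rng.random((n, len(gs))) < [spec.baseline_on_prob.get(g, 0.5) for g in gs]
                 ).astype(np.uint8) for ct, gs in genes.items()}

    # co: pair cells uniformly at random, then sweep the rules twice
    joint = (rng.random((n, len(all_genes))) < p0).astype(np.uint8)
    perm = rng.permutation(n)  # CT2 partner of CT1 cell i is row perm[i]
    col = {g: i for i, g in enumerate(all_genes)}
    # partner-aware view: for a CT1-resident target, an intercellular source is
    # read from the paired CT2 cell and vice versa; intracellular rules read
    # within the same cell.
    k1 = len(spec.ct1_genes)
    ct1_rows = np.arange(n)
    ct2_rows = perm
    row_of = {"CT1": ct1_rows, "CT2": ct2_rows}
    for _sweep in range(2):  # second pass lets feedback edges settle
        for r in spec.rules:
            tgt_reg = register_of[r.target]
            src_reg = register_of[r.source]
            tgt_rows = row_of[tgt_reg]
            src_rows = row_of[src_reg] if src_reg != tgt_reg else tgt_rows
            src_state = joint[src_rows, col[r.source]]
            p = np.where(src_state == 1, r.p_on_given_src_on, r.p_on_given_src_off)
            joint[tgt_rows, col[r.target]] = (rng.random(n) < p).astype(np.uint8)
    co = {"CT1": joint[ct1_rows][:, :k1], "CT2": joint[ct2_rows][:, k1:]}

    binary = {}
    tables = {}
    for ct in ("CT1", "CT2"):
        for cond, mat in (("mono", mono[ct]), ("co", co[ct])):
            frame = pd.DataFrame(mat, columns=genes[ct],
                                 index=[f"{ct}_{cond}_cell{i}" for i in range(n)])
            binary[(ct, cond)] = frame
            tables[(ct, cond)] = _table_from_binary(frame)
    return SyntheticDataset(spec, binary, tables)


def generate_planted_circuit(spec: PlantedCircuitSpec
                             ) -> tuple[StateVector, ProbDist, ProbDist]:
    """Targets generated by a known circuit acting on a known baseline.

    Exact mode returns the Born marginals of U|Psi_mo> directly. Sampled
    mode emulates finite cell counts that go through the same squared-L2
    convention as real data: since the encoding maps state *counts* to
    amplitudes (alpha proportional to C, not to sqrt(C)), the count
    distribution consistent with a target Born marginal m is proportional
    to sqrt(m). Each register's table is therefore a seeded multinomial
    draw of ``n_cells`` states from sqrt(m)/sum(sqrt(m)), so the empirical
    squared-L2 targets converge to the exact Born marginals as n grows.
    """
    initial = tensor_initial_state(spec.psi_ct1, spec.psi_ct2)
    final = simulate(spec.topology, initial)
    q1 = marginal(final, "CT1", spec.psi_ct1.gene_order)
    q2 = marginal(final, "CT2", spec.psi_ct2.gene_order)
    if spec.exact:
        return initial, q1, q2
    if spec.n_cells <= 0:
        raise ValueError("sampled mode needs n_cells > 0")
    from .encoding import target_distribution  # local import avoids cycle at module load
    rng = np.random.default_rng(spec.seed)
    out = []
    for dist, gene_order in ((q1, spec.psi_ct1.gene_order),
                             (q2, spec.psi_ct2.gene_order)):
        w = np.sqrt(dist.probs)
        draws = rng.multinomial(spec.n_cells, w / w.sum())
        counts = {bitstring_of_index(i, len(gene_order)): int(c)
                  for i, c in enumerate(draws) if c}
        table = BinaryStateTable(gene_order, counts, spec.n_cells)
        out.append(target_distribution(table))
    return initial, out[0], out[1]
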
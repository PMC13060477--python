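"""End-to-end orchestration: encode -> prune -> search -> refine -> ablate.

``run_pipeline`` ties the stages into one reproducible run directory with a
manifest (config hash, seed, versions, final cost), so a run can be
reconstructed from its artifacts alone. Each stage is also exposed on its
own through the CLI so intermediate artifacts can be inspected or swapped.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from . import __version__
from .ablation import GeneMap, sequential_contribution, to_network
from .encoding import (amplitudes_from_counts, binarize, normalize_log1p,
                       target_distribution, tensor_initial_state)
from .io import read_expression, read_gene_list, state_table_to_json, write_state_table_tsv
from .pruning import candidates_from_delta, density_delta, CandidateSet
from .quantum_core import Topology, cost
from .refine import optimize_angles
from .search import SearchConfig, search_topology
from .state import BinaryStateTable


@dataclass
class RunConfig:
    ct1_mono: str
    ct1_co: str
    ct2_mono: str
    ct2_co: str
    ct1_genes: str
    ct2_genes: str
    outdir: str
    threshold: float = 0.0
    target_sum: float | None = None  # None -> median cell total
    delta_cutoff: float = 0.01
    kl_eps: float = 1e-10
    optimizer: str = "cobyla"
    seed: int = 0
    search: SearchConfig = field(default_factory=SearchConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        search = SearchConfig(**raw.pop("search", {}))
        try:
            cfg = cls(search=search, **raw)
        except TypeError as exc:
            raise ValueError(f"invalid run config: {exc}") from None
        return cfg

    def validate(self) -> None:
        for name in ("ct1_mono", "ct1_co", "ct2_mono", "ct2_co",
                     "ct1_genes", "ct2_genes"):
            if not Path(getattr(self, name)).exists():
                raise FileNotFoundError(
                    f"config field '{name}': path {getattr(self, name)!r} does not exist")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def encode_stage(cfg: RunConfig) -> dict[tuple[str, str], BinaryStateTable]:
    """Load, normalize, binarize all four matrices against their gene panels."""
    panels = {"CT1": read_gene_list(cfg.ct1_genes), "CT2": read_gene_list(cfg.ct2_genes)}
    paths = {("CT1", "mono"): cfg.ct1_mono, ("CT1", "co"): cfg.ct1_co,
             ("CT2", "mono"): cfg.ct2_mono, ("CT2", "co"): cfg.ct2_co}
    tables = {}
    for (ct, cond), path in paths.items():
        adata = normalize_log1p(read_expression(path), target_sum=cfg.target_sum)
        tables[(ct, cond)] = binarize(adata, panels[ct], threshold=cfg.threshold)
    return tables


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow and write every artifact to ``cfg.outdir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    tables = encode_stage(cfg)
    for (ct, cond), table in tables.items():
        write_state_table_tsv(table, out / f"states_{ct}_{cond}.tsv")
        (out / f"states_{ct}_{cond}.json").write_text(state_table_to_json(table))

    psi1 = amplitudes_from_counts(tables[("CT1", "mono")])
    psi2 = amplitudes_from_counts(tables[("CT2", "mono")])
    initial = tensor_initial_state(psi1, psi2)
    q1 = target_distribution(tables[("CT1", "co")])
    q2 = target_distribution(tables[("CT2", "co")])

    psi1_co = amplitudes_from_counts(tables[("CT1", "co")])
    psi2_co = amplitudes_from_counts(tables[("CT2", "co")])
    psi_co = tensor_initial_state(psi1_co, psi2_co)
    delta = density_delta(initial, psi_co, cutoff=cfg.delta_cutoff)
    candidates = candidates_from_delta(delta)
    gene_map = GeneMap(tuple(psi1.gene_order), tuple(psi2.gene_order))
    qubit_gene = {q: gene_map.gene(q) for q in range(initial.n_qubits)}
    _write_candidates(candidates, qubit_gene, out / "candidates.tsv")

    scfg = cfg.search
    scfg.seed = cfg.seed if scfg.seed == 0 else scfg.seed
    result = search_topology(candidates, initial, q1, q2, scfg)
    (out / "topology_search.json").write_text(result.to_json())
    _write_trace(result.trace, out / "trace.tsv")

    refined = optimize_angles(result.topology, initial, q1, q2,
                              optimizer=cfg.optimizer, seed=cfg.seed)
    (out / "topology_refined.json").write_text(refined.topology.to_json())
    (out / "circuit.qasm").write_text(refined.topology.to_qasm3(initial.n_qubits))

    table = sequential_contribution(refined.topology, initial, q1, q2, gene_map)
    (out / "ablation.tsv").write_text(table.to_tsv())
    net = to_network(table, refined.topology, gene_map)
    nx.write_graphml(net, out / "network.graphml")

    final_cost = cost(refined.topology, initial, q1, q2, eps=cfg.kl_eps)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "versions": {"qccinfer": __version__, "numpy": np.__version__,
                     "python": platform.python_version()},
        "n_candidates": len(candidates),
        "n_gates": len(refined.topology),
        "kl_baseline": result.kl_initial,
        "kl_search": result.kl_final,
        "kl_refined": final_cost.total,
        "kl_ct1": final_cost.kl_ct1,
        "kl_ct2": final_cost.kl_ct2,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _write_candidates(candidates: CandidateSet, qubit_gene: dict[int, str],
                      path: Path) -> None:
    import pandas as pd

    recs = candidates.to_records(qubit_gene)
    cols = ["control_qubit", "target_qubit", "control_gene", "target_gene",
            "max_abs_delta"]
    pd.DataFrame(recs, columns=cols).to_csv(path, sep="\t", index=False)


def _write_trace(trace: list[dict], path: Path) -> None:
    import pandas as pd

    pd.DataFrame(trace).to_csv(path, sep="\t", index=False)
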
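# Methods

`qccinfer` infers cell–cell communication (CCC) between two cell populations
by learning a unitary state transformation instead of scoring curated
ligand–receptor pairs. This note records the model, its assumptions, the
parameters that matter, and the design decisions taken where the design was
genuinely open.

## Model

**Encoding.** For each cell type (CT1, CT2) and condition (non-interacting
"mono", interacting "co"), raw counts are total-count normalized (each cell
scaled to the median cell total by default, the scanpy convention) and
log1p-transformed. A curated gene panel restricts the matrix to d genes per
type; each gene is binarized — active iff its log-normalized expression
exceeds 0 (strictly) — turning every cell into a bitstring s ∈ {0,1}^d.
Per-state cell counts C(s) summarize each population.

Mono-culture counts are L2-normalized into the amplitudes of a register
state, α_s = C(s)/√(Σ C(s')²), and the joint baseline is the separable
tensor product |Ψ⟩ = |ψ_CT1⟩ ⊗ |ψ_CT2⟩ (CT1 occupies the high bits; the
basis convention is big-endian with gene-order position k on qubit k).
Co-culture counts pass through the same L2 normalization and are then
squared into the target distributions Q(s) = α_s². Note that Q is the
squared-L2 image of the counts, not the relative frequency: the two agree
only when all observed counts are equal, and the implementation
deliberately reproduces the squared convention on both sides (baseline Born
probabilities are squared count-proportional amplitudes too), so the model
compares like with like.

**Transformation and cost.** Communication is modeled by a unitary built
from controlled-RX gates: CRX(θ) applies RX(θ) to its target qubit when the
control qubit is |1⟩. A circuit is an ordered gate list (topology τ,
angles θ); duplicates are allowed and order matters. The training cost is

L(τ, θ) = D_KL(P_ψ'(CT1) ‖ Q(CT1)) + D_KL(P_ψ'(CT2) ‖ Q(CT2)),

the sum over registers of the KL divergence between the Born marginals of
the circuit output ψ' = U(τ,θ)|Ψ⟩ and the empirical targets. Marginals are
read exactly from amplitudes (infinite-shot limit); a seeded multinomial
shots mode exists for realism experiments only. Both arguments of each KL
receive additive smoothing eps (default 1e-10) and renormalization, so
states with zero empirical mass that the circuit populates contribute a
large but finite penalty.

**Candidate pruning.** With real amplitudes both global states are real
vectors, so Δρ = |Ψ_co⟩⟨Ψ_co| − |Ψ_mo⟩⟨Ψ_mo| is real, symmetric and
traceless. A CRX gate moves amplitude exactly between joint basis states
that differ on its target bit while the control bit is set; inverting that
picture, every off-diagonal |Δρ_ij| above the cutoff δ_ρ (default 0.01)
nominates the bit positions where i and j differ as targets and the
positions where both are 1 as controls. The deduplicated ordered pairs,
ranked by their largest nominating element, form the candidate set C.
Intra-register and cross-register pairs are both kept: the model learns
gene-regulatory and communication edges alike. The interacting global
state is formed as the tensor product of the per-type co-culture amplitude
vectors, mirroring the baseline construction. This decode rule is one
plausible reduction of the density difference; it is isolated behind a
single function so alternatives can be swapped in. Raising δ_ρ never adds
candidates.

**Topology search.** Three interchangeable algorithms choose and order
gates from C with all angles fixed at π/2 (partial entanglement, sensitive
to weak correlations):

1. *n-wise local search* — best-improvement local search whose moves insert
   a candidate at any position or delete any gate; compound moves touching
   up to n gates (default 2) are enumerated lazily, i.e. only when no
   single move improves. Most thorough, most expensive.
2. *multi-epoch construction* (default) — each epoch reshuffles C (seeded),
   forces the shuffle's first candidate as the starting gate, then
   repeatedly appends the cost-minimizing candidate (reuse allowed — two
   CRX(π/2) on a pair compose to CRX(π)) up to max_gates, tracking the best
   prefix. Appends may pass through cost-increasing steps, because an
   enabling gate can pay off only later. The best sequence across epochs
   is then Occam-pruned: any gate whose removal worsens the cost by at most
   occam_tol (default 1e-4) is dropped, preferring removals that reduce it.
3. *QUBO selection + permutation ordering* — gate selection is posed as a
   quadratic binary problem with linear terms a_g = L({g}) − L(∅) and
   pairwise terms b_gh = L({g,h}) − L({g}) − L({h}) + L(∅) (pairs evaluated
   in candidate-rank order, a fixed documented convention), optionally with
   a cardinality penalty λ(Σx − max_gates)². It is solved by exact
   enumeration (≤ 20 variables) or seeded single-flip simulated annealing;
   the selected set is then ordered by exhaustive permutation (k ≤ 8; more
   selected gates is an explicit error steering users to algorithms 1–2).
   If no ordering beats the gate-free baseline the empty topology is
   returned, so every algorithm's result cost is ≤ baseline.

All searches are deterministic given their seed. Defaults:
improvement_tol 1e-6, max_gates 10 (the ≤ 10-qubit regime this model
targets keeps circuits small), epochs 20.

**Angle refinement.** The discrete solution's gates are promoted to
CRX(θ_i) and θ is optimized over [−2π, 2π]^k (outcome probabilities are
2π-periodic and even in each angle) from the θ = 0 initialization. Because
the initial state is real, every outcome probability has zero derivative at
θ = 0 — an exact stationary point — so the default optimizer is COBYLA,
whose rhobeg = 1 trust region steps straight off the plateau; bounded
L-BFGS-B with numerical gradients (step 1e-6, ftol 1e-12, maxiter 500) is
available for smooth refinement away from zero, optionally with a seeded
Gaussian jitter (σ ~ 1e-3, off by default) on the initialization. No
pruning is applied after refinement: near-zero optimized angles are
reported as-is.

**Ablation and network transcription.** Gates are re-enabled prefix-by-
prefix in topology order at their refined angles; row i records the cost
with gates 1..i. Per-gate deltas telescope exactly to the total change, and
two percentages are reported side by side because both conventions are
useful: |Δ_i|/KL_baseline·100 (share of the starting cost; absolute value
so cost-increasing gates are still ranked by magnitude) and
−Δ_i/(KL_baseline − KL_final)·100 (signed share of the achieved reduction;
sums to 100%). Cost-increasing gates are reported, never dropped. The
circuit is finally transcribed to a directed multigraph — one edge per gate
from control gene to target gene, intercellular iff the genes sit in
different registers — exported as GraphML and edge-list TSV.

## Synthetic ground truth

The rule-based generator emulates a two-cell-type co-culture with known
regulatory structure. Mono condition: every gene is an independent
Bernoulli switch with its baseline activation probability. Co condition:
cells of the two types are paired uniformly at random (seeded), then the
directed rule list is swept twice; each rule resamples its target gene from
the conditional probabilities (p_on|src_on, p_on|src_off) given the current
source state — read from the paired partner cell for intercellular rules,
from the same cell for intracellular ones. Two sweeps let feedback edges
settle; when several rules target one gene they apply in list order (last
write wins within a sweep). These conventions are fixed and documented so
runs are exactly reproducible.

The packaged benchmark uses CT1 = {g50, g90}, CT2 = {g60, g70, g71, g80}
(a 6-qubit system): ligand–receptor edge g50→g60 (0.9/0.1), intracellular
CT2 cascade g60→g70→g71→g80 (0.9/0.1 each), return edges g60→g90 and
g80→g90 (0.85/0.15), and feedback g80→g50, g90→g50 (0.8/0.2). Baseline
activation is 0.5 for the driver g50 and 0.3 elsewhere; n = 5000 cells per
type and condition. Effect sizes follow the magnitude a strong, clearly
detectable co-culture induction would show; they produce a large
distributional shift (baseline cost ≈ 3.4 under the smoothed KL).
Exported count matrices cast the binary states to integer counts with
lognormal magnitudes and add three always-on housekeeping genes (outside
the analysis panels) so every cell has positive sequencing depth and the
full normalize → binarize path is exercised.

The planted-circuit generator provides instances whose ground truth *is* a
known CRX circuit on a known baseline. Exact mode returns the Born
marginals of the transformed state. Sampled mode draws per-register counts
from √m/Σ√m — the count distribution whose squared-L2 image is the Born
marginal m — so the empirical targets built through the standard squared
convention converge to the exact ones as n grows.

What the generator does **not** emulate: dropout curves, library-size
variation beyond a lognormal scale, batch effects, doublets, or spatial
structure. Passing tests therefore demonstrate correctness of the
inference machinery under the stated generative assumptions, not
robustness to real scRNA-seq noise.

## Numerical choices and degenerate inputs

- Statevector simulation is dense (complex128, axis-wise gate application),
  exact to machine precision for the ≤ ~14-qubit systems in scope; a
  different backend may be substituted if it honours the big-endian basis
  convention.
- KL smoothing eps = 1e-10, configurable and recorded in run manifests.
- Search tie-breaks: first-found in a deterministic enumeration order
  (n-wise), earliest in the epoch's shuffled order (multi-epoch),
  candidate-rank order (QUBO permutation stage).
- All-zero cells cannot be total-count normalized and are rejected by name;
  empty gene panels and panel genes missing from a matrix are errors.
- An empty candidate set is valid and yields the empty topology; targets
  equal to the baseline marginals yield zero cost and no gates.
- Angle recovery is reported up to sign and 2π-periodicity, the inherent
  degeneracy of CRX outcome probabilities.

## Known limitations

- Append-only forward construction (algorithm 2) cannot represent
  solutions whose early gates are individually cost-increasing unless a
  later append rescues them within the same construction; on benchmark
  instances with a large programmed shift it converges to measurably
  higher cost than the n-wise local search (≈ 1.05 vs ≈ 0.46 from a 3.43
  baseline at seed 1). The n-wise search is the more reliable choice when
  its cost is affordable.
- The QUBO objective is a second-order surrogate of the true set cost;
  third-order and higher interactions between gates are invisible to the
  selection stage.
- The squared-L2 target convention emphasizes dominant states relative to
  plain frequencies; interpretation of KL magnitudes should account for
  it.
- Hilbert-space growth restricts panels to roughly N + M ≤ 10–14 genes;
  gene selection is an explicit input, and no automatic marker selection
  is provided.
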
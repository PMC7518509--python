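# Methods

## Model

`mapsd` implements network propagation of additive multi-omics evidence
over a weighted interactome, specialized to tissue/cell resolution.

**Affinity.** The PPI graph is simple and undirected: duplicate pairs are
collapsed regardless of input order and self-loops are dropped (both
counts logged), because the random-walk degrees below assume a simple
graph. The affinity matrix A places weight 1 on every edge and amplifies
it to λ (default 1.5) when the endpoints are annotated to intersecting
micro-domain sets. *Co-localization is intersection-nonempty*: proteins
often carry several compartment annotations, and any shared compartment
suffices for physical contact. Edges touching an unannotated protein keep
weight 1 — absence of localization evidence is not evidence of absence. A
single global adjusted matrix is used for all tissue columns; subcellular
annotation catalogs are not tissue-resolved, so tissue specificity enters
only through the abundance weights. λ is configurable, and λ = 1 reduces
A to the plain adjacency, which is how the localization ablation is run.

**Markov operator.** `M = D⁻¹A` with `D_ii = Σ_j a_ij`. Zero-degree nodes
make D⁻¹ undefined, so isolates are excluded from the operator with a
logged list; their diffused signal is defined to equal their input signal
(they neither send nor receive). Row sums are asserted to 1 within 1e-12
at build time and within 1e-10 after powers — the looser bound absorbs
floating-point accumulation over repeated sparse products. A is stored in
CSR; at the intended scale (~16k nodes, ~250k edges) operator and states
fit comfortably in workstation memory.

**Operator orientation.** The update is applied literally as `Sᵗ = Mᵗ S*`:
row-stochastic M acting on the left means node *i*'s new signal is the
degree-weighted average of its neighbors' signals. The transpose
(mass-conserving spreading) variant is available behind
`orientation="transpose"` / `--operator transpose` for comparison, but the
averaging form is the default because it is the printed operator.

**Signals.** Evidence is binary per (gene, layer) — multiple studies
hitting the same layer still contribute one point. Layer order is
canonicalized alphabetically for reproducible serialization (the row sum
is order-invariant anyway). The abundance weight map is
High = 1, Medium = 0.75, Low = 0.5, Not detected = 0.25; unknown labels
raise rather than defaulting silently. A (gene, column) cell absent from
the abundance table falls back to the "Not detected" floor 0.25
(configurable), on the view that no detection record is the weakest
admissible state rather than a reason to zero the gene out.

**Universe alignment.** The working universe is the intersection of the
network node set with the union of evidence and abundance genes, in
network node order; network nodes without evidence start at `S_i = 0`, and
evidence/abundance genes outside the network are dropped with a logged
count. This makes G = n so the operator applies directly. When the
abundance table covers the proteome (the usual case, and the synthetic
default) the universe is simply the network node set.

**Stopping rule.** R compares step t against t+1, summed jointly over all
genes and columns; per-column stopping exists behind a flag but is not the
default. Accepting at `R(t) ≤ 0.05` returns Sᵗ — the state *before* the
extra step — since the criterion exists to stop short of over-smoothing.
`R = 0` is defined at `SST = 0` (all-zero signal is already maximally
smooth, and terminates at t = 1). A safety cap `t_max = 50` guards
non-convergent cases: on a bipartite component a lazy-free walk oscillates
and R need not fall (the 2-node path holds R = 1 forever), so runs that
hit the cap return the capped state with a flag. On connected
non-bipartite graphs the walk is ergodic and R → 0, so the cap is never
reached in practice; real interactomes are overwhelmingly non-bipartite.

**Ranking.** "Peaks in the brain" is read per gene from its own diffused
profile (row-wise argmax over columns), not as a cross-gene rank.
Brain-unique requires a strict maximum over every non-brain column; ties
are compared after rounding to 12 significant digits so that ~1e-15
arithmetic noise cannot fabricate strictness. Genes with an all-zero
profile form a fourth, unranked class. The holdout harness removes a
gene's entire evidence row (all layers) by default — the strongest form of
removal — and a trial counts as recovered when the diffused maximum of the
removed gene still lies in a brain column.

## Synthetic data

The generator emulates the structure, not the statistics, of real inputs:
Erdős–Rényi (default, exchangeable null) or Barabási–Albert (hub-heavy)
graphs; Poisson-distributed micro-domain counts per protein; categorical
abundance levels per (gene, column) with background probabilities
(0.15, 0.25, 0.30, 0.30) over High/Medium/Low/Not detected; and per-layer
Bernoulli evidence (p = 0.5) for each seed gene, with at least one forced
hit so every seed has `S_i ≥ 1`. A planted module wires a designated gene
set internally at probability 0.6, gives it a shared micro-domain and High
abundance in every brain column (at most Low elsewhere), and concentrates
the seed genes inside it. An option draws the evidence genes disjoint from
the module instead, to measure background brain-unique counts under a null
pairing of evidence and structure.

Default test-scale conditions are 200-node graphs (edge p 0.02–0.05), 5
evidence layers, 20 seed genes, 10 tissue/cell columns of which 2 are
brain, and a 25-gene planted module; the dense-oracle suite spans n up to
300. These sizes are chosen so dense matrix-power oracles remain exact
cross-checks of the sparse incremental path. What passing tests show is
that the algebra, stopping rule, and classification behave as specified
and that a strongly planted module is recoverable; they do not show
performance on real interactomes, where evidence is noisier, abundance
calls are incomplete, and module structure is far weaker.

## Numerical choices and degenerate inputs

- Row-sum tolerances: 1e-12 at operator build, 1e-10 after powers.
- Incremental states are advanced by one sparse product per step; the
  equivalence `‖Sᵗ − dense(Mᵗ)S*‖∞ ≤ 1e-10` is asserted in tests.
- Tie comparisons in ranking use 12-significant-digit rounding.
- Components with no nonzero seed stay exactly zero (no drift is possible:
  their state is the zero vector under a linear operator).
- Non-finite values during diffusion raise with the step index.
- Empty networks, empty gene universes, unknown abundance labels,
  conflicting duplicate abundance rows, and zero-degree nodes at operator
  build all raise typed errors rather than propagating silently.

## Known limitations

- Identifiers are opaque strings; no Ensembl/UniProt namespace mapping.
- Evidence layers must be thresholded upstream; the package computes no
  DE/GWAS/methylation statistics.
- The qualitative abundance weights are fixed design constants, not fitted.
- No restart parameter or alternative kernels (heat, personalized
  PageRank); the diffusion is the plain Markov power iteration with the
  smoothness-rate stop.
- Stopping time is instance-dependent; on bipartite toy graphs the
  criterion cannot be met and the run is capped by design.
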
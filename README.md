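# mapsd

Tissue/cell-specific Markov signal diffusion over protein–protein
interaction (PPI) networks, for prioritizing candidate disease risk genes
from multi-omics evidence.

## The problem and the method

Complex-disease signals arrive as fragmented gene lists from different
omics layers — differential expression, GWAS loci, rare/de novo mutations,
differential methylation, open chromatin — each pre-thresholded upstream
(e.g. FDR ≤ 0.05, genome-wide significance 5×10⁻⁸). `mapsd` integrates
them over the interactome and asks, per tissue and cell type, which genes
concentrate disease signal:

1. **Evidence matrix and signal vector.** E is a binary G×L matrix,
   `e_ij = 1` iff gene *i* has a hit in layer *j*; the signal vector is the
   row sum `S_i = Σ_j e_ij` (a gene that is both DE and differentially
   methylated scores 2).
2. **Localization-adjusted affinity.** For the PPI graph, `a_ij = 1` on an
   edge, amplified to `a_ij = λ = 1.5` when the two proteins are annotated
   to at least one common subcellular micro-domain, `0` otherwise; A is
   symmetric.
3. **Markov operator.** `M = D⁻¹A`, with `D_ii = Σ_j a_ij` — the
   random-walk normalization of the adjusted adjacency. Rows of M sum to 1.
4. **Tissue/cell signal matrix.** Qualitative protein-abundance calls map
   onto weights High = 1, Medium = 0.75, Low = 0.5, Not detected = 0.25,
   giving a G×T weight matrix W over the (tissue, cell type) columns, and
   `S*_ij = w_ij · S_i`.
5. **Diffusion with a smoothness-rate stop.** Iterate `Sᵗ = Mᵗ S*`. With
   `Err = M^{t+1}S* − MᵗS*` and `K = M^{t+1}S* + MᵗS*`, the smoothness rate
   is `R = SSE/SST = ΣErr² / ΣK²`; iteration stops at the first *t* with
   `R ≤ 0.05`, before over-smoothing flattens the profile.
6. **Ranking.** Each gene is classified by where its diffused profile
   peaks: *brain-unique* (strict maximum inside the brain columns),
   *brain-and-elsewhere* (tied), or *non-brain*; brain-unique genes split
   into known (seed, `S_i > 0`) and novel. A leave-one-out harness removes
   one brain seed gene per trial and measures how often diffusion restores
   its brain maximum.

## Worked example

`python examples/01_worked_example.py` builds a 5-protein network (one
co-localized pair, one gene with two omics hits, a brain and a liver
column) and prints every stage:

```
degrees D_ii (row sums of A): [1.5 2.5 3.  2.  2. ]
signal vector S (evidence points per gene): {'P1': 0, 'P2': 2, 'P3': 0, 'P4': 1, 'P5': 0}
...
diffusion stopped at t=14 (smoothness rate R=0.0399 <= 0.05)
```

The 1.5 degree entry reflects the amplified co-localized edge; P2's signal
of 2 is one point per omics layer with a hit; diffusion stops as soon as
consecutive states differ by ≲5% in relative squared magnitude. The other
examples show the R trajectory on a 200-node random interactome
(`02_synthetic_diffusion.py`, which stops at t=3), leave-one-out recovery
on a planted brain module (`03_holdout_recovery.py`, 20/20 recovered), and
the abundance-weight ablation (`04_abundance_ablation.py`: with uniform
weights the brain-unique count collapses from 164 to 0, because all tissue
columns become identical).

## Command line

```
mapsd simulate --seed 11 --out inputs/          # synthetic input bundle
mapsd run --edges inputs/edges.tsv --localization inputs/localization.tsv \
          --abundance inputs/abundance.tsv --evidence-dir inputs/evidence \
          --catalog inputs/catalog.tsv --out results/
mapsd holdout ... --n-trials 20 --seed 2 --out holdout.tsv
mapsd rank --matrix results/diffused_matrix.tsv --catalog inputs/catalog.tsv --out ranked.tsv
```

All defaults (λ = 1.5, R-threshold 0.05, missing-abundance weight 0.25,
t cap 50, left operator orientation) can be overridden by flags or a YAML
config file; flags beat the file, the file beats the defaults.

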
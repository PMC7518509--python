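"""Diffusion on a synthetic interactome: the smoothness-rate trajectory.

Generates an Erdős–Rényi network (n=200, p=0.05) with 20 seed genes and 10
tissue/cell columns, runs the diffusion, and prints the R = SSE/SST
trajectory.  R falls sharply as consecutive states converge; iteration
stops at the first step where R <= 0.05 to avoid over-smoothing the
signal into a constant per-component profile.
"""

from mapsd import RunConfig, generate_inputs, run_pipeline
from mapsd.synthetic import SyntheticSpec

spec = SyntheticSpec(n_nodes=200, er_p=0.05, n_seed_genes=20, n_columns=10,
                     n_brain_columns=2, module_size=0, seeds_in_module=False,
                     rng_seed=42)
inp = generate_inputs(spec)
res = run_pipeline(inp.network, inp.localization, inp.abundance,
                   inp.layer_gene_lists, inp.catalog, RunConfig())

print(f"network: {inp.network.n} nodes, {inp.network.n_edges} edges; "
      f"{len(inp.seed_genes)} seed genes")
print("\n  t      SSE        SST        R")
for t, sse, sst, r in res.diffusion.diagnostics.steps:
    print(f"  {t}   {sse:9.4f}  {sst:9.4f}  {r:.4f}")
print(f"\nstopped at t={res.diffusion.t_stop}: the signal is smooth enough that "
      "one more step changes it by <~5% in relative squared magnitude")
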
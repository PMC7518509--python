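"""Leave-one-out recovery on a planted disease module.

Plants a densely wired 25-gene module whose members share a micro-domain
and have High abundance in the brain columns, with all 20 seed genes inside
it.  Each trial removes one brain-peaking seed gene's evidence entirely and
reruns the diffusion; a trial succeeds when the removed gene's diffused
maximum still lies in a brain column, i.e. its neighbors' signal restores
it.  A high fraction shows the method re-identifies genuine risk genes from
network context alone.
"""

from mapsd import generate_inputs, holdout_recovery
from mapsd.synthetic import SyntheticSpec

spec = SyntheticSpec(n_nodes=200, er_p=0.02, module_size=25, module_edge_p=0.6,
                     n_seed_genes=20, n_columns=10, n_brain_columns=2, rng_seed=1)
inp = generate_inputs(spec)
report = holdout_recovery(inp.network, inp.localization, inp.abundance,
                          inp.layer_gene_lists, inp.catalog,
                          n_trials=20, rng_seed=7)
print(report.to_string(index=False))
print(f"\nrecovery fraction: {report['recovered'].mean():.2f} "
      f"({int(report['recovered'].sum())}/{len(report)} held-out genes regained "
      "a brain-column maximum)")
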
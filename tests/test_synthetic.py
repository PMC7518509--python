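"""Generator determinism, statistical contracts, and the worked example."""

import math

import numpy as np
import pytest

from mapsd.markov import transition_matrix
from mapsd.network import build_affinity
from mapsd.pipeline import run_pipeline
from mapsd.signals import build_evidence_matrix, build_weight_matrix, signal_vector, tissue_signal_matrix
from mapsd.synthetic import (
    WORKED_EXAMPLE_EXPECTED,
    SyntheticSpec,
    generate_inputs,
    worked_example_fixture,
)


class TestGenerateInputs:
    def test_same_seed_same_bundle(self):
        spec = SyntheticSpec(n_nodes=80, er_p=0.05, module_size=10, rng_seed=9)
        a, b = generate_inputs(spec), generate_inputs(spec)
        assert a.network.nodes == b.network.nodes
        assert a.network.edges == b.network.edges
        assert a.layer_gene_lists == b.layer_gene_lists
        assert a.abundance.equals(b.abundance)
        assert {k: v for k, v in a.localization.assignments.items()} == \
               {k: v for k, v in b.localization.assignments.items()}

    def test_different_seed_differs(self):
        a = generate_inputs(SyntheticSpec(n_nodes=80, er_p=0.05, rng_seed=1))
        b = generate_inputs(SyntheticSpec(n_nodes=80, er_p=0.05, rng_seed=2))
        assert a.network.edges != b.network.edges

    def test_er_p_zero_gives_empty_edge_set(self):
        inp = generate_inputs(SyntheticSpec(n_nodes=30, er_p=0.0, n_seed_genes=5,
                                            seeds_in_module=False, rng_seed=0))
        assert inp.network.n_edges == 0

    def test_er_edge_count_within_three_sd(self):
        n, p = 500, 0.02
        inp = generate_inputs(SyntheticSpec(n_nodes=n, er_p=p, n_seed_genes=5,
                                            seeds_in_module=False, rng_seed=7))
        n_pairs = n * (n - 1) // 2
        mean, sd = n_pairs * p, math.sqrt(n_pairs * p * (1 - p))
        assert abs(inp.network.n_edges - mean) <= 3 * sd

    def test_planted_module_structure(self, planted_inputs):
        inp = planted_inputs
        assert set(inp.seed_genes) <= set(inp.module_genes)
        # members share the module micro-domain
        domains = [inp.localization.domains_of(g) for g in inp.module_genes]
        assert set.intersection(*domains)
        # High abundance in every brain column, never above Low elsewhere
        brain = {(t, c) for t, c in inp.catalog.brain_columns}
        module = set(inp.module_genes)
        for row in inp.abundance.itertuples(index=False):
            if row.gene_id in module:
                if (row.tissue, row.cell_type) in brain:
                    assert row.level == "High"
                else:
                    assert row.level in ("Low", "Not detected")

    def test_generated_inputs_pass_loaders(self, tmp_path, planted_inputs):
        from mapsd.io import write_bundle
        from mapsd.network import load_edge_list, load_localizations
        from mapsd.signals import load_abundance, load_catalog, load_evidence_layers

        out = tmp_path / "bundle"
        files = write_bundle(planted_inputs, str(out))
        assert "edges.tsv" in files and "manifest.yaml" in files
        net = load_edge_list(str(out / "edges.tsv"))
        assert net.edges == planted_inputs.network.subnetwork(net.nodes).edges
        loc = load_localizations(str(out / "localization.tsv"), strict=False)
        assert loc.assignments == {k: v for k, v in
                                   planted_inputs.localization.assignments.items() if v}
        cat = load_catalog(str(out / "catalog.tsv"))
        assert cat.columns == planted_inputs.catalog.columns
        assert cat.brain_columns == planted_inputs.catalog.brain_columns
        ab = load_abundance(str(out / "abundance.tsv"))
        assert len(ab) == len(planted_inputs.abundance)
        layers = load_evidence_layers(
            {p.stem: str(p) for p in (out / "evidence").glob("*.txt")})
        assert layers == planted_inputs.layer_gene_lists

    def test_evidence_frequency_matches_bernoulli_rate(self):
        spec = SyntheticSpec(n_nodes=300, er_p=0.03, n_seed_genes=100,
                             evidence_layer_p=0.4, seeds_in_module=False, rng_seed=5)
        inp = generate_inputs(spec)
        E = build_evidence_matrix(inp.layer_gene_lists,
                                  [g for g in inp.network.nodes])
        S = signal_vector(E)
        seeds = [g for g in inp.seed_genes if g in set(inp.network.nodes)]
        hits = sum(S.values[E.gene_ids.index(g)] for g in seeds)
        # per-layer Bernoulli(0.4) with at-least-one forcing: mean per seed
        # is slightly above L*p; allow generous sampling slack
        per_seed = hits / len(seeds)
        assert 5 * 0.4 - 0.6 <= per_seed <= 5 * 0.4 + 0.8

    def test_background_disjoint_option(self):
        spec = SyntheticSpec(n_nodes=120, er_p=0.04, module_size=15,
                             n_seed_genes=20, background_evidence_disjoint=True,
                             rng_seed=3)
        inp = generate_inputs(spec)
        evidence_genes = set().union(*inp.layer_gene_lists.values())
        assert evidence_genes.isdisjoint(inp.module_genes)

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError, match="module larger"):
            SyntheticSpec(n_nodes=10, module_size=20)
        with pytest.raises(ValueError, match="brain"):
            SyntheticSpec(n_columns=3, n_brain_columns=3)


class TestWorkedExample:
    def test_affinity_matches_hand_matrix(self, worked_example):
        A = build_affinity(worked_example.network, worked_example.localization)
        np.testing.assert_array_equal(A.values.toarray(),
                                      WORKED_EXAMPLE_EXPECTED["affinity"])
        assert np.count_nonzero(A.values.toarray() == 1.5) == 2  # one amplified pair

    def test_degrees_signal_weights(self, worked_example):
        fx = worked_example
        A = build_affinity(fx.network, fx.localization)
        from mapsd.markov import degree_vector
        np.testing.assert_array_equal(degree_vector(A),
                                      WORKED_EXAMPLE_EXPECTED["degrees"])
        universe = fx.network.nodes
        E = build_evidence_matrix(fx.layer_gene_lists, universe)
        S = signal_vector(E)
        np.testing.assert_array_equal(S.values, WORKED_EXAMPLE_EXPECTED["signal"])
        assert 2 in S.values  # the DE + methylated gene
        W = build_weight_matrix(fx.abundance, fx.catalog, universe)
        np.testing.assert_array_equal(W.values, WORKED_EXAMPLE_EXPECTED["weights"])
        S_star = tissue_signal_matrix(W, S)
        np.testing.assert_array_equal(S_star.values,
                                      WORKED_EXAMPLE_EXPECTED["tissue_signal"])

    def test_end_to_end_matches_dense_oracle(self, worked_example):
        fx = worked_example
        res = run_pipeline(fx.network, fx.localization, fx.abundance,
                           fx.layer_gene_lists, fx.catalog)
        A = build_affinity(fx.network, fx.localization)
        M_dense = np.diag(1.0 / WORKED_EXAMPLE_EXPECTED["degrees"]) @ A.values.toarray()
        oracle = (np.linalg.matrix_power(M_dense, res.diffusion.t_stop)
                  @ WORKED_EXAMPLE_EXPECTED["tissue_signal"])
        np.testing.assert_allclose(res.diffusion.smoothed.values, oracle, atol=1e-10)
        assert res.diffusion.diagnostics.r_values[-1] <= 0.05
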
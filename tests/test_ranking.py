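"""Brain-unique classification, per-column summaries, and holdout recovery."""

import numpy as np
import pytest

from mapsd.diffusion import DiffusionResult, SmoothnessDiagnostics
from mapsd.pipeline import RunConfig, holdout_recovery, run_pipeline
from mapsd.ranking import (
    CLASS_BRAIN_AND_ELSEWHERE,
    CLASS_BRAIN_UNIQUE,
    CLASS_NON_BRAIN,
    CLASS_NO_SIGNAL,
    classify_genes,
    round_significant,
    summarize_by_column,
)
from mapsd.signals import SignalVector, TissueCellCatalog, TissueSignalMatrix


def make_result(values, genes, catalog):
    smoothed = TissueSignalMatrix(values=np.asarray(values, float),
                                  gene_ids=list(genes), catalog=catalog)
    return DiffusionResult(smoothed=smoothed, t_stop=1,
                           diagnostics=SmoothnessDiagnostics(), capped=False, config={})


@pytest.fixture()
def cat3():
    cols = [("cerebral cortex", "neuronal cells"),
            ("cerebellum", "purkinje cells"),
            ("liver", "hepatocytes")]
    return TissueCellCatalog(columns=cols, brain_columns=cols[:2])


class TestClassifyGenes:
    def test_three_way_classification(self, cat3):
        values = [
            [3.0, 1.0, 2.0],   # strict max in brain -> brain_unique
            [2.0, 0.5, 2.0],   # tied between brain and liver -> brain_and_elsewhere
            [0.5, 0.2, 1.0],   # max in liver -> non_brain
            [0.0, 0.0, 0.0],   # nothing anywhere
        ]
        seed = SignalVector(values=np.array([2, 0, 1, 0]),
                            gene_ids=["A", "B", "C", "D"])
        ranked = classify_genes(make_result(values, "ABCD", cat3), cat3, seed)
        assert list(ranked.table["class"]) == [
            CLASS_BRAIN_UNIQUE, CLASS_BRAIN_AND_ELSEWHERE, CLASS_NON_BRAIN, CLASS_NO_SIGNAL,
        ]
        assert list(ranked.table["is_seed"]) == [True, False, True, False]

    def test_positive_genes_partition_into_three_classes(self, cat3, rng):
        values = rng.random((40, 3)) * 2
        seed = SignalVector(values=rng.integers(0, 2, 40),
                            gene_ids=[f"G{i}" for i in range(40)])
        ranked = classify_genes(make_result(values, seed.gene_ids, cat3), cat3, seed)
        classes = set(ranked.table["class"])
        assert classes <= {CLASS_BRAIN_UNIQUE, CLASS_BRAIN_AND_ELSEWHERE, CLASS_NON_BRAIN}
        assert len(ranked.table) == 40

    def test_float_noise_ties_absorbed_by_rounding(self, cat3):
        eps = 1e-15
        values = [[1.0 + eps, 0.0, 1.0]]
        seed = SignalVector(values=np.array([1]), gene_ids=["A"])
        ranked = classify_genes(make_result(values, ["A"], cat3), cat3, seed)
        # 1+1e-15 rounds to 1.0 at 12 significant digits: a tie, not unique
        assert ranked.table["class"][0] == CLASS_BRAIN_AND_ELSEWHERE

    def test_counts_match_brute_force_scan(self, planted_inputs):
        res = run_pipeline(planted_inputs.network, planted_inputs.localization,
                           planted_inputs.abundance, planted_inputs.layer_gene_lists,
                           planted_inputs.catalog)
        brain = planted_inputs.catalog.brain_mask()
        vals = round_significant(res.diffusion.smoothed.values)
        n_unique = sum(
            1 for row in vals
            if row.max() > 0 and row[brain].max() > row[~brain].max()
        )
        assert res.ranked.count(CLASS_BRAIN_UNIQUE) == n_unique

    def test_empty_brain_columns_rejected(self):
        cols = [("liver", "hepatocytes"), ("lung", "pneumocytes")]
        cat = TissueCellCatalog(columns=cols, brain_columns=[])
        seed = SignalVector(values=np.array([1]), gene_ids=["A"])
        with pytest.raises(ValueError, match="brain"):
            classify_genes(make_result([[1.0, 0.0]], ["A"], cat), cat, seed)

    def test_column_ranks_are_dense_per_column(self, cat3, rng):
        values = rng.random((10, 3))
        seed = SignalVector(values=np.zeros(10, int), gene_ids=[f"G{i}" for i in range(10)])
        ranked = classify_genes(make_result(values, seed.gene_ids, cat3), cat3, seed)
        for j in range(3):
            assert sorted(ranked.column_ranks[:, j]) == list(range(1, 11))
            top = np.argmin(ranked.column_ranks[:, j])
            assert values[top, j] == values[:, j].max()


class TestSummarize:
    def test_single_gene_single_count(self, cat3):
        seed = SignalVector(values=np.array([1]), gene_ids=["A"])
        ranked = classify_genes(make_result([[2.0, 1.0, 0.5]], ["A"], cat3), cat3, seed)
        summary = summarize_by_column(ranked)
        assert summary["n_top"].sum() == 1
        assert summary.loc[0, "n_seed_top"] == 1

    def test_ties_counted_per_column(self, cat3):
        seed = SignalVector(values=np.array([0]), gene_ids=["A"])
        ranked = classify_genes(make_result([[2.0, 2.0, 1.0]], ["A"], cat3), cat3, seed)
        summary = summarize_by_column(ranked)
        assert summary["n_top"].sum() == 2  # one gene, two tied argmax columns
        assert summary["n_novel_top"].sum() == 2

    def test_counts_match_brute_force_tally(self, cat3, rng):
        values = round_significant(rng.random((30, 3)))
        seed = SignalVector(values=rng.integers(0, 2, 30),
                            gene_ids=[f"G{i}" for i in range(30)])
        ranked = classify_genes(make_result(values, seed.gene_ids, cat3), cat3, seed)
        summary = summarize_by_column(ranked)
        for j in range(3):
            expected = sum(1 for row in values if row[j] == row.max() and row.max() > 0)
            assert summary.loc[j, "n_top"] == expected


class TestHoldoutRecovery:
    def test_planted_module_recovery_high(self, planted_inputs):
        report = holdout_recovery(
            planted_inputs.network, planted_inputs.localization,
            planted_inputs.abundance, planted_inputs.layer_gene_lists,
            planted_inputs.catalog, n_trials=10, rng_seed=7,
        )
        assert len(report) == 10
        assert report["recovered"].mean() >= 0.9

    def test_recovery_fraction_is_mean_of_trials(self, planted_inputs):
        report = holdout_recovery(
            planted_inputs.network, planted_inputs.localization,
            planted_inputs.abundance, planted_inputs.layer_gene_lists,
            planted_inputs.catalog, n_trials=5, rng_seed=3,
        )
        assert report["recovered"].mean() == report["recovered"].astype(float).sum() / 5

    def test_explicit_non_seed_removal_rejected(self, planted_inputs):
        non_seed = next(g for g in planted_inputs.network.nodes
                        if g not in set(planted_inputs.seed_genes))
        with pytest.raises(ValueError, match="not seeds"):
            holdout_recovery(
                planted_inputs.network, planted_inputs.localization,
                planted_inputs.abundance, planted_inputs.layer_gene_lists,
                planted_inputs.catalog, seeds_to_remove=[non_seed],
            )

    def test_unknown_gene_rejected(self, planted_inputs):
        with pytest.raises(ValueError, match="not in the universe"):
            holdout_recovery(
                planted_inputs.network, planted_inputs.localization,
                planted_inputs.abundance, planted_inputs.layer_gene_lists,
                planted_inputs.catalog, seeds_to_remove=["NOPE"],
            )

    def test_isolated_seed_not_recovered(self):
        """A held-out gene whose component has no other seed gets zero signal."""
        import pandas as pd
        from mapsd.network import LocalizationAnnotation, network_from_pairs
        from mapsd.signals import TissueCellCatalog

        # two triangles; the only seed lives alone on the second one
        pairs = [("A", "B"), ("B", "C"), ("A", "C"),
                 ("X", "Y"), ("Y", "Z"), ("X", "Z")]
        net = network_from_pairs(pairs)
        cols = [("cerebral cortex", "neuronal cells"), ("liver", "hepatocytes")]
        cat = TissueCellCatalog(columns=cols, brain_columns=[cols[0]])
        rows = [(g, t, c, "High") for g in net.nodes for t, c in cols]
        abundance = pd.DataFrame(rows, columns=["gene_id", "tissue", "cell_type", "level"])
        layers = {"gwas": {"X", "A"}}
        report = holdout_recovery(
            net, LocalizationAnnotation([], {}), abundance, layers, cat,
            seeds_to_remove=["X"],
        )
        assert not report["recovered"].iloc[0]
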
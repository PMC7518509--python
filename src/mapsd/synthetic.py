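"""Seeded generators for every input the pipeline consumes.

The generator emulates the structure of the real study inputs: an
interactome with configurable degree structure (Erdős–Rényi for
exchangeable nulls, Barabási–Albert for hub-heavy realism), random
micro-domain assignments, qualitative abundance calls per (tissue, cell)
column, and pre-thresholded evidence gene lists per omics layer.  A
*planted module* wires a designated gene set densely together, gives its
members a shared micro-domain and High abundance in the brain columns (and
at most Low elsewhere), and concentrates the seed genes inside it — the
ground truth that recovery and ablation tests measure against.

Only the post-threshold binary structure of omics evidence is emulated;
p-values and effect sizes are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import LocalizationAnnotation, PPINetwork, network_from_pairs
from .signals import TissueCellCatalog

DEFAULT_DOMAINS = [
    "Nucleoplasm", "Nuclear membrane", "Nucleoli", "Cytosol", "Mitochondria",
    "Endoplasmic reticulum", "Golgi apparatus", "Vesicles", "Plasma membrane",
    "Cell junctions", "Actin filaments", "Microtubules", "Centrosome",
    "Lysosomes", "Peroxisomes", "Lipid droplets",
]

BRAIN_COLUMN_POOL = [
    ("cerebral cortex", "neuronal cells"),
    ("cerebellum", "purkinje cells"),
    ("hippocampus", "neuronal cells"),
    ("caudate", "neuronal cells"),
]
NON_BRAIN_COLUMN_POOL = [
    ("liver", "hepatocytes"),
    ("lung", "pneumocytes"),
    ("kidney", "cells in tubules"),
    ("heart muscle", "myocytes"),
    ("colon", "glandular cells"),
    ("skin", "keratinocytes"),
    ("testis", "cells in seminiferous ducts"),
    ("pancreas", "exocrine glandular cells"),
    ("spleen", "cells in white pulp"),
    ("thyroid gland", "glandular cells"),
]

DEFAULT_LAYERS = [
    "de_novo_mutation",
    "differential_expression",
    "differential_methylation",
    "gwas",
    "open_chromatin",
]

LEVELS = ["High", "Medium", "Low", "Not detected"]
BACKGROUND_LEVEL_PROBS = [0.15, 0.25, 0.30, 0.30]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic input bundle."""

    n_nodes: int = 200
    edge_model: str = "er"  # "er" (Erdős–Rényi) or "ba" (Barabási–Albert)
    er_p: float = 0.05
    ba_m: int = 3
    n_domains: int = 8
    domains_per_node_mean: float = 1.5  # Poisson, truncated at n_domains
    n_columns: int = 10
    n_brain_columns: int = 2
    n_layers: int = 5
    n_seed_genes: int = 20
    evidence_layer_p: float = 0.5  # per-layer Bernoulli for each seed gene
    module_size: int = 0  # 0 disables the planted module
    module_edge_p: float = 0.6
    module_brain_high: bool = True
    seeds_in_module: bool = True
    background_evidence_disjoint: bool = False  # null harness: seeds avoid the module
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes <= 0 or self.n_layers <= 0 or self.n_columns <= 0:
            raise ValueError("all counts must be positive")
        if not (0 <= self.er_p <= 1 and 0 <= self.module_edge_p <= 1
                and 0 <= self.evidence_layer_p <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.module_size > self.n_nodes:
            raise ValueError("planted module larger than the graph")
        if self.n_seed_genes > self.n_nodes:
            raise ValueError("more seed genes than nodes")
        if not (0 < self.n_brain_columns < self.n_columns):
            raise ValueError("need at least one brain and one non-brain column")
        if self.edge_model not in ("er", "ba"):
            raise ValueError(f"unknown edge model {self.edge_model!r}")


@dataclass
class SyntheticInputs:
    """In-memory bundle of generated pipeline inputs."""

    network: PPINetwork
    localization: LocalizationAnnotation
    abundance: pd.DataFrame
    layer_gene_lists: dict[str, set[str]]
    catalog: TissueCellCatalog
    module_genes: list[str] = field(default_factory=list)
    seed_genes: list[str] = field(default_factory=list)
    spec: SyntheticSpec | None = None


def _make_catalog(n_columns: int, n_brain: int) -> TissueCellCatalog:
    def cycle(pool, k):
        out = []
        for i in range(k):
            t, c = pool[i % len(pool)]
            suffix = f" #{i // len(pool) + 1}" if i >= len(pool) else ""
            out.append((t + suffix, c))
        return out

    brain = cycle(BRAIN_COLUMN_POOL, n_brain)
    other = cycle(NON_BRAIN_COLUMN_POOL, n_columns - n_brain)
    return TissueCellCatalog(columns=brain + other, brain_columns=brain)


def _layer_names(n_layers: int) -> list[str]:
    if n_layers <= len(DEFAULT_LAYERS):
        return DEFAULT_LAYERS[:n_layers]
    extra = [f"layer_{k}" for k in range(n_layers - len(DEFAULT_LAYERS))]
    return DEFAULT_LAYERS + extra


def generate_inputs(spec: SyntheticSpec) -> SyntheticInputs:
    """Deterministically generate one full input bundle from ``spec``."""
    rng = np.random.default_rng(spec.rng_seed)
    nodes = [f"G{i:05d}" for i in range(spec.n_nodes)]

    nx_seed = int(rng.integers(0, 2**31 - 1))
    if spec.edge_model == "er":
        g = nx.fast_gnp_random_graph(spec.n_nodes, spec.er_p, seed=nx_seed)
    else:
        g = nx.barabasi_albert_graph(spec.n_nodes, spec.ba_m, seed=nx_seed)
    edge_set = {(min(u, v), max(u, v)) for u, v in g.edges()}

    module_idx: list[int] = []
    if spec.module_size:
        module_idx = sorted(rng.choice(spec.n_nodes, size=spec.module_size, replace=False))
        for a in range(len(module_idx)):
            for b in range(a + 1, len(module_idx)):
                if rng.random() < spec.module_edge_p:
                    u, v = module_idx[a], module_idx[b]
                    edge_set.add((min(u, v), max(u, v)))
    module_genes = [nodes[i] for i in module_idx]

    pairs = [(nodes[u], nodes[v]) for u, v in sorted(edge_set)]
    network = network_from_pairs(pairs)

    # micro-domains: Poisson count per node, module members share one domain
    catalog_domains = list(DEFAULT_DOMAINS[: spec.n_domains])
    while len(catalog_domains) < spec.n_domains:
        catalog_domains.append(f"Domain {len(catalog_domains)}")
    assignments: dict[str, set[str]] = {}
    module_domain = catalog_domains[0]
    for i, node in enumerate(nodes):
        k = min(int(rng.poisson(spec.domains_per_node_mean)), spec.n_domains)
        domains = {str(d) for d in rng.choice(catalog_domains, size=k, replace=False)} if k else set()
        if i in set(module_idx):
            domains.add(module_domain)
        if domains:
            assignments[node] = domains
    localization = LocalizationAnnotation(domain_catalog=catalog_domains,
                                          assignments=assignments)

    catalog = _make_catalog(spec.n_columns, spec.n_brain_columns)
    brain_mask = catalog.brain_mask()
    module_set = set(module_idx)
    rows = []
    for i, gene in enumerate(nodes):
        planted = spec.module_brain_high and i in module_set
        for j, (tissue, cell) in enumerate(catalog.columns):
            if planted:
                level = "High" if brain_mask[j] else LEVELS[2 + int(rng.random() < 0.5)]
            else:
                level = LEVELS[int(rng.choice(4, p=BACKGROUND_LEVEL_PROBS))]
            rows.append((gene, tissue, cell, level))
    abundance = pd.DataFrame(rows, columns=["gene_id", "tissue", "cell_type", "level"])

    # seed genes and their per-layer Bernoulli evidence
    if spec.background_evidence_disjoint and module_idx:
        pool = [i for i in range(spec.n_nodes) if i not in module_set]
    elif spec.seeds_in_module and module_idx:
        pool = list(module_idx)
    else:
        pool = list(range(spec.n_nodes))
    n_seeds = min(spec.n_seed_genes, len(pool))
    seed_idx = sorted(rng.choice(pool, size=n_seeds, replace=False))
    seed_genes = [nodes[i] for i in seed_idx]

    layers = _layer_names(spec.n_layers)
    layer_gene_lists: dict[str, set[str]] = {name: set() for name in layers}
    for gene in seed_genes:
        hits = rng.random(spec.n_layers) < spec.evidence_layer_p
        if not hits.any():
            hits[int(rng.integers(spec.n_layers))] = True
        for j in np.flatnonzero(hits):
            layer_gene_lists[layers[j]].add(gene)

    return SyntheticInputs(
        network=network, localization=localization, abundance=abundance,
        layer_gene_lists=layer_gene_lists, catalog=catalog,
        module_genes=module_genes, seed_genes=seed_genes, spec=spec,
    )


def worked_example_fixture() -> SyntheticInputs:
    """Fixed 5-protein network with hand-checkable intermediates.

    P1–P2–P3–P4–P5 path plus the chord P3–P5, which closes a triangle and
    makes the graph non-bipartite (a lazy-free walk on a bipartite graph
    oscillates and never smooths).  P1 and P2 share the Nucleus
    micro-domain, so the P1–P2 edge is amplified to 1.5 while every other
    edge keeps weight 1.  P2 carries differential-expression and
    methylation evidence (signal 2), P4 a GWAS hit (signal 1).  Two
    columns: a brain column where P2's abundance is High and a liver
    column where it is Low.
    """
    pairs = [("P1", "P2"), ("P2", "P3"), ("P3", "P4"), ("P4", "P5"), ("P3", "P5")]
    network = network_from_pairs(pairs)
    localization = LocalizationAnnotation(
        domain_catalog=["Nucleus", "Cytosol"],
        assignments={"P1": {"Nucleus"}, "P2": {"Nucleus"}, "P3": {"Cytosol"}},
    )
    catalog = TissueCellCatalog(
        columns=[("cerebral cortex", "neuronal cells"), ("liver", "hepatocytes")],
        brain_columns=[("cerebral cortex", "neuronal cells")],
    )
    levels = {
        "P1": ("High", "Low"),
        "P2": ("High", "Low"),
        "P3": ("Medium", "Medium"),
        "P4": ("Low", "High"),
        "P5": ("Not detected", "High"),
    }
    rows = []
    for gene, (b, l) in levels.items():
        rows.append((gene, "cerebral cortex", "neuronal cells", b))
        rows.append((gene, "liver", "hepatocytes", l))
    abundance = pd.DataFrame(rows, columns=["gene_id", "tissue", "cell_type", "level"])
    layer_gene_lists = {
        "de_novo_mutation": set(),
        "differential_expression": {"P2"},
        "differential_methylation": {"P2"},
        "gwas": {"P4"},
        "open_chromatin": set(),
    }
    return SyntheticInputs(
        network=network, localization=localization, abundance=abundance,
        layer_gene_lists=layer_gene_lists, catalog=catalog,
        module_genes=[], seed_genes=["P2", "P4"], spec=None,
    )


WORKED_EXAMPLE_EXPECTED = {
    # dense affinity over nodes P1..P5, amplification 1.5
    "affinity": np.array([
        [0.0, 1.5, 0.0, 0.0, 0.0],
        [1.5, 0.0, 1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0, 1.0, 1.0],
        [0.0, 0.0, 1.0, 0.0, 1.0],
        [0.0, 0.0, 1.0, 1.0, 0.0],
    ]),
    "degrees": np.array([1.5, 2.5, 3.0, 2.0, 2.0]),
    "signal": np.array([0, 2, 0, 1, 0]),
    "weights": np.array([
        [1.0, 0.5],
        [1.0, 0.5],
        [0.75, 0.75],
        [0.5, 1.0],
        [0.25, 1.0],
    ]),
    "tissue_signal": np.array([
        [0.0, 0.0],
        [2.0, 1.0],
        [0.0, 0.0],
        [0.5, 1.0],
        [0.0, 0.0],
    ]),
}
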
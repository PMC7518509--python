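"""Protein-protein interaction network loading and localization-adjusted affinity.

The interactome is treated as a simple undirected graph over opaque protein
identifiers.  Edge weights encode subcellular co-localization: an interaction
between two proteins annotated to at least one common micro-domain (nucleus,
cytosol, vesicles, ...) is amplified by a factor ``lambda`` (default 1.5) on
the grounds that proteins sharing a compartment are more likely to interact
physically; all other interactions keep weight 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

DEFAULT_AMPLIFICATION = 1.5


class NetworkError(ValueError):
    """Raised for malformed or degenerate network inputs."""


@dataclass
class PPINetwork:
    """Deduplicated undirected PPI graph.

    ``nodes`` fixes the index order 0..n-1; ``edges`` holds canonical
    (i, j) index pairs with i < j, each unordered pair stored once.
    """

    nodes: list[str]
    edges: set[tuple[int, int]]
    n_raw_rows: int = 0
    n_duplicates_removed: int = 0
    n_self_loops_removed: int = 0
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {name: i for i, name in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            raise NetworkError("duplicate node identifiers")
        n = self.n
        for i, j in self.edges:
            if i == j:
                raise NetworkError(f"self-loop on node index {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise NetworkError(f"edge ({i},{j}) references invalid node index")
            if i > j:
                raise NetworkError(f"edge ({i},{j}) is not canonical (i < j)")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, node: str) -> int:
        return self._index[node]

    def degree_counts(self) -> np.ndarray:
        """Unweighted degree of each node."""
        deg = np.zeros(self.n, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def subnetwork(self, keep: list[str]) -> "PPINetwork":
        """Induced subgraph on ``keep`` (order of ``keep`` defines new indices)."""
        keep_set = set(keep)
        unknown = keep_set - set(self.nodes)
        if unknown:
            raise NetworkError(f"unknown nodes requested: {sorted(unknown)[:5]}")
        new_index = {name: i for i, name in enumerate(keep)}
        edges = set()
        for i, j in self.edges:
            a, b = self.nodes[i], self.nodes[j]
            if a in keep_set and b in keep_set:
                x, y = new_index[a], new_index[b]
                edges.add((min(x, y), max(x, y)))
        return PPINetwork(nodes=list(keep), edges=edges)

    def adjacency(self) -> sp.csr_matrix:
        """Unweighted symmetric adjacency matrix (CSR)."""
        return build_affinity(self, LocalizationAnnotation([], {}), amplification=1.0).values


@dataclass
class LocalizationAnnotation:
    """Subcellular micro-domain assignments per protein.

    A protein may carry zero, one, or several domains; proteins absent from
    the source table are simply unannotated.
    """

    domain_catalog: list[str]
    assignments: dict[str, set[str]]

    def __post_init__(self) -> None:
        catalog = set(self.domain_catalog)
        for node, domains in self.assignments.items():
            extra = domains - catalog
            if extra:
                raise NetworkError(
                    f"node {node!r} assigned domains outside the catalog: {sorted(extra)}"
                )

    def domains_of(self, node: str) -> set[str]:
        return self.assignments.get(node, set())


@dataclass
class AffinityMatrix:
    """Symmetric weighted adjacency with entries in {0, 1, amplification}."""

    values: sp.csr_matrix
    amplification: float
    nodes: list[str]

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _sniff_delimiter(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def load_edge_list(
    path: str,
    *,
    delimiter: str | None = None,
    header: bool | None = None,
    allow_self_loops: bool = False,
) -> PPINetwork:
    """Read a two-column interaction table into a deduplicated ``PPINetwork``.

    Duplicate pairs (in either order) are collapsed and self-loops dropped
    unless ``allow_self_loops``; both counts are logged.  ``header=None``
    auto-detects a header row by checking whether the first row repeats
    anywhere as a data pair (headers never do in practice, but the explicit
    flags are authoritative when provided).
    """
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split(delimiter)]
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise NetworkError(f"{path}:{lineno}: malformed row {line!r}")
            rows.append((parts[0], parts[1]))
    if header is None:
        header = bool(rows) and rows[0][0].lower() in {
            "protein1", "protein_a", "source", "node1", "gene1", "id1", "a",
        }
    if header and rows:
        rows = rows[1:]
    if not rows:
        raise NetworkError(f"{path}: empty edge list")
    return network_from_pairs(rows, allow_self_loops=allow_self_loops)


def network_from_pairs(
    pairs: list[tuple[str, str]], *, allow_self_loops: bool = False
) -> PPINetwork:
    """Build a ``PPINetwork`` from in-memory (a, b) identifier pairs."""
    nodes: list[str] = []
    index: dict[str, int] = {}
    for a, b in pairs:
        for name in (a, b):
            if name not in index:
                index[name] = len(nodes)
                nodes.append(name)
    edges: set[tuple[int, int]] = set()
    self_loops = 0
    duplicates = 0
    for a, b in pairs:
        i, j = index[a], index[b]
        if i == j:
            self_loops += 1
            continue
        key = (min(i, j), max(i, j))
        if key in edges:
            duplicates += 1
        else:
            edges.add(key)
    if self_loops and not allow_self_loops:
        logger.info("removed %d self-loop rows", self_loops)
    if duplicates:
        logger.info("collapsed %d duplicate interaction rows", duplicates)
    return PPINetwork(
        nodes=nodes,
        edges=edges,
        n_raw_rows=len(pairs),
        n_duplicates_removed=duplicates,
        n_self_loops_removed=self_loops,
    )


def load_localizations(
    path: str,
    catalog: list[str] | None = None,
    *,
    strict: bool = True,
    delimiter: str | None = None,
) -> LocalizationAnnotation:
    """Read a (protein_id, micro_domain) table into per-protein domain sets.

    With ``strict`` the catalog is closed and unknown domains raise; with
    ``strict=False`` (or no catalog) the catalog is extended as domains
    appear, in first-seen order.
    """
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=delimiter, header=None, names=["protein", "domain"],
                         dtype=str, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["protein", "domain"])
    df = df.dropna()
    # tolerate a header row
    if len(df) and df.iloc[0, 0].lower() in {"protein", "protein_id", "gene", "id"}:
        df = df.iloc[1:]
    catalog = list(catalog) if catalog is not None else []
    known = set(catalog)
    seen_domains = list(dict.fromkeys(df["domain"].str.strip()))
    unknown = [d for d in seen_domains if d not in known]
    if unknown and strict and catalog:
        raise NetworkError(f"unknown micro-domains under strict mode: {unknown}")
    for d in unknown:
        catalog.append(d)
    assignments: dict[str, set[str]] = {}
    for protein, domain in zip(df["protein"].str.strip(), df["domain"].str.strip()):
        assignments.setdefault(protein, set()).add(domain)
    return LocalizationAnnotation(domain_catalog=catalog, assignments=assignments)


def build_affinity(
    network: PPINetwork,
    loc: LocalizationAnnotation,
    amplification: float = DEFAULT_AMPLIFICATION,
) -> AffinityMatrix:
    """Localization-adjusted affinity matrix A.

    a_ij = amplification if {i,j} is an edge whose endpoint micro-domain sets
    intersect; 1 for any other edge (including edges touching unannotated
    proteins); 0 off the edge set.  A is exactly symmetric.
    """
    if amplification <= 0:
        raise NetworkError("amplification must be positive")
    if network.n == 0:
        raise NetworkError("empty network")
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    for i, j in network.edges:
        di = loc.domains_of(network.nodes[i])
        dj = loc.domains_of(network.nodes[j])
        w = amplification if (di and dj and di & dj) else 1.0
        rows.extend((i, j))
        cols.extend((j, i))
        data.extend((w, w))
    values = sp.csr_matrix(
        (np.asarray(data), (np.asarray(rows, dtype=np.int64), np.asarray(cols, dtype=np.int64))),
        shape=(network.n, network.n),
    )
    return AffinityMatrix(values=values, amplification=float(amplification), nodes=list(network.nodes))
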
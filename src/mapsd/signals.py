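"""Evidence, signal, and tissue/cell weighting.

A gene's initial disease signal is the count of omics layers (differential
expression, GWAS, rare/de novo mutation, methylation, open chromatin, ...)
in which it carries a pre-thresholded hit: S_i = sum_j e_ij over the binary
G x L evidence matrix E.  Qualitative protein-abundance calls per
(tissue, cell type) column are mapped onto weights
High=1, Medium=0.75, Low=0.5, Not detected=0.25, and the tissue-specific
signal matrix is the column-wise scaling S*_ij = w_ij * S_i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXPRESSION_WEIGHTS = {
    "high": 1.0,
    "medium": 0.75,
    "low": 0.5,
    "not detected": 0.25,
}
DEFAULT_MISSING_WEIGHT = 0.25  # same floor as "Not detected"


class SignalError(ValueError):
    """Raised for invalid evidence/abundance inputs."""


@dataclass
class EvidenceMatrix:
    values: np.ndarray  # G x L, entries in {0, 1}
    gene_ids: list[str]
    layer_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.gene_ids), len(self.layer_names)):
            raise SignalError("evidence matrix shape does not match labels")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise SignalError("duplicate gene ids")
        if len(set(self.layer_names)) != len(self.layer_names):
            raise SignalError("duplicate layer names")
        if not np.isin(self.values, (0, 1)).all():
            raise SignalError("evidence entries must be binary")


@dataclass
class SignalVector:
    values: np.ndarray  # length G, non-negative integers
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if (self.values < 0).any():
            raise SignalError("signal entries must be non-negative")


@dataclass
class TissueCellCatalog:
    """Ordered (tissue, cell_type) columns with a flagged brain subset."""

    columns: list[tuple[str, str]]
    brain_columns: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.columns)) != len(self.columns):
            raise SignalError("duplicate (tissue, cell_type) columns")
        missing = set(self.brain_columns) - set(self.columns)
        if missing:
            raise SignalError(f"brain columns not in catalog: {sorted(missing)}")

    @property
    def T(self) -> int:
        return len(self.columns)

    def brain_mask(self) -> np.ndarray:
        brain = set(self.brain_columns)
        return np.array([c in brain for c in self.columns], dtype=bool)

    def labels(self, sep: str = "|") -> list[str]:
        return [f"{t}{sep}{c}" for t, c in self.columns]


@dataclass
class ExpressionWeightMatrix:
    values: np.ndarray  # G x T
    gene_ids: list[str]
    catalog: TissueCellCatalog
    n_missing: int = 0
    missing_weight: float = DEFAULT_MISSING_WEIGHT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        permitted = set(EXPRESSION_WEIGHTS.values()) | {float(self.missing_weight)}
        if not np.isin(self.values, sorted(permitted)).all():
            raise SignalError("weight entries outside the permitted set")


@dataclass
class TissueSignalMatrix:
    values: np.ndarray  # G x T, non-negative
    gene_ids: list[str]
    catalog: TissueCellCatalog

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise SignalError("tissue signals must be non-negative")


def build_evidence_matrix(
    layer_gene_lists: dict[str, set[str]],
    gene_universe: list[str],
    *,
    sort_layers: bool = True,
) -> EvidenceMatrix:
    """Binary G x L membership matrix: e_ij = 1 iff gene i has a hit in layer j.

    Genes listed in a layer but absent from the universe are dropped with a
    logged count; layer order is canonicalized alphabetically unless
    ``sort_layers`` is off.
    """
    if not gene_universe:
        raise SignalError("empty gene universe")
    layers = sorted(layer_gene_lists) if sort_layers else list(layer_gene_lists)
    index = {g: i for i, g in enumerate(gene_universe)}
    values = np.zeros((len(gene_universe), len(layers)), dtype=np.int8)
    for j, layer in enumerate(layers):
        genes = set(layer_gene_lists[layer])
        dropped = [g for g in genes if g not in index]
        if dropped:
            logger.info("layer %s: dropped %d gene(s) outside the universe", layer, len(dropped))
        for g in genes - set(dropped):
            values[index[g], j] = 1
    return EvidenceMatrix(values=values, gene_ids=list(gene_universe), layer_names=layers)


def signal_vector(E: EvidenceMatrix) -> SignalVector:
    """Additive signal S_i = sum_j e_ij (evidence points per gene)."""
    return SignalVector(values=E.values.sum(axis=1).astype(np.int64), gene_ids=list(E.gene_ids))


def expression_weight(level: str) -> float:
    """Map a qualitative abundance call onto its diffusion weight."""
    key = " ".join(str(level).strip().lower().split())
    if key not in EXPRESSION_WEIGHTS:
        raise SignalError(
            f"unknown abundance level {level!r}; expected one of "
            f"{sorted(EXPRESSION_WEIGHTS)}"
        )
    return EXPRESSION_WEIGHTS[key]


def build_weight_matrix(
    abundance_table: pd.DataFrame,
    catalog: TissueCellCatalog,
    gene_universe: list[str],
    *,
    missing_weight: float = DEFAULT_MISSING_WEIGHT,
) -> ExpressionWeightMatrix:
    """G x T weight matrix from (gene, tissue, cell_type, level) rows.

    Missing (gene, column) combinations fall back to ``missing_weight``
    (default: the "Not detected" floor of 0.25); conflicting duplicate rows
    raise.
    """
    required = {"gene_id", "tissue", "cell_type", "level"}
    if not required.issubset(abundance_table.columns):
        raise SignalError(f"abundance table must have columns {sorted(required)}")
    col_index = {c: j for j, c in enumerate(catalog.columns)}
    extra = set(zip(abundance_table["tissue"], abundance_table["cell_type"])) - set(catalog.columns)
    if extra:
        raise SignalError(f"(tissue, cell_type) pairs outside the catalog: {sorted(extra)[:5]}")
    gene_index = {g: i for i, g in enumerate(gene_universe)}
    values = np.full((len(gene_universe), catalog.T), float(missing_weight))
    filled = np.zeros_like(values, dtype=bool)
    n_outside = 0
    conflicts = []
    for row in abundance_table.itertuples(index=False):
        i = gene_index.get(row.gene_id)
        if i is None:
            n_outside += 1
            continue
        j = col_index[(row.tissue, row.cell_type)]
        w = expression_weight(row.level)
        if filled[i, j] and values[i, j] != w:
            conflicts.append((row.gene_id, row.tissue, row.cell_type))
        values[i, j] = w
        filled[i, j] = True
    if conflicts:
        raise SignalError(f"conflicting abundance levels for: {conflicts[:5]}")
    if n_outside:
        logger.info("abundance table: %d row(s) for genes outside the universe", n_outside)
    n_missing = int((~filled).sum())
    if n_missing:
        logger.info("abundance table: %d missing (gene, column) cell(s) set to %g",
                    n_missing, missing_weight)
    return ExpressionWeightMatrix(values=values, gene_ids=list(gene_universe),
                                  catalog=catalog, n_missing=n_missing,
                                  missing_weight=float(missing_weight))


def tissue_signal_matrix(W: ExpressionWeightMatrix, S: SignalVector) -> TissueSignalMatrix:
    """Column-wise scaling S*_ij = w_ij * S_i."""
    if W.gene_ids != S.gene_ids:
        raise SignalError("weight matrix and signal vector gene orders are misaligned")
    values = W.values * np.asarray(S.values, dtype=float)[:, None]
    return TissueSignalMatrix(values=values, gene_ids=list(W.gene_ids), catalog=W.catalog)


def load_catalog(path: str, *, delimiter: str | None = None) -> TissueCellCatalog:
    """Read a (tissue, cell_type, is_brain) table."""
    if delimiter is None:
        with open(path) as fh:
            delimiter = "\t" if "\t" in fh.readline() else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    required = {"tissue", "cell_type", "is_brain"}
    if not required.issubset(df.columns):
        raise SignalError(f"catalog must have columns {sorted(required)}")
    columns = list(zip(df["tissue"], df["cell_type"]))
    truthy = {"1", "true", "yes"}
    brain = [c for c, flag in zip(columns, df["is_brain"].str.lower()) if flag in truthy]
    return TissueCellCatalog(columns=columns, brain_columns=brain)


def load_evidence_layers(paths: dict[str, str]) -> dict[str, set[str]]:
    """Read one plain-text gene list per layer (one id per line)."""
    out: dict[str, set[str]] = {}
    for layer, path in paths.items():
        with open(path) as fh:
            out[layer] = {line.strip() for line in fh if line.strip()}
    return out


def load_abundance(path: str, *, delimiter: str | None = None) -> pd.DataFrame:
    if delimiter is None:
        with open(path) as fh:
            delimiter = "\t" if "\t" in fh.readline() else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    required = {"gene_id", "tissue", "cell_type", "level"}
    if not required.issubset(df.columns):
        raise SignalError(f"abundance table must have columns {sorted(required)}")
    return df
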
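"""Post-diffusion gene ranking and leave-one-out recovery.

A gene's tissue assignment is read off its own diffused profile: the
row-wise maximum over the (tissue, cell type) columns.  A gene is
*brain-unique* when that maximum is attained strictly inside the brain
columns; *brain-and-elsewhere* when the maximum ties between a brain and a
non-brain column; *non-brain* otherwise.  Brain-unique genes split into
known (nonzero initial signal, i.e. seeds) and novel (signal acquired
purely through diffusion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffusion import DiffusionResult
from .signals import SignalVector, TissueCellCatalog

logger = logging.getLogger(__name__)

ROUND_SIG_DIGITS = 12

CLASS_BRAIN_UNIQUE = "brain_unique"
CLASS_BRAIN_AND_ELSEWHERE = "brain_and_elsewhere"
CLASS_NON_BRAIN = "non_brain"
CLASS_NO_SIGNAL = "no_signal"


def round_significant(x: np.ndarray, digits: int = ROUND_SIG_DIGITS) -> np.ndarray:
    """Round to ``digits`` significant figures (zeros pass through).

    Used before max/tie comparisons so that arithmetic noise of order
    1e-15 cannot turn an exact tie into a spurious strict maximum.
    """
    x = np.asarray(x, dtype=float)
    out = x.copy()
    nz = x != 0
    mag = np.floor(np.log10(np.abs(x[nz])))
    scale = 10.0 ** (digits - 1 - mag)
    out[nz] = np.round(x[nz] * scale) / scale
    return out


@dataclass
class RankedGeneTable:
    """Per-gene classification plus per-column intensities and ranks."""

    table: pd.DataFrame  # gene_id, class, is_seed, max_intensity, argmax_columns
    intensities: np.ndarray  # G x T diffused values (rounded)
    column_ranks: np.ndarray  # G x T dense rank (1 = highest) within each column
    catalog: TissueCellCatalog

    def count(self, cls: str, *, seed: bool | None = None) -> int:
        mask = self.table["class"] == cls
        if seed is not None:
            mask &= self.table["is_seed"] == seed
        return int(mask.sum())


def classify_genes(
    result: DiffusionResult,
    catalog: TissueCellCatalog,
    seed_signal: SignalVector,
) -> RankedGeneTable:
    """Label every gene by where its diffused maximum lies.

    Ties at the row maximum are decided after rounding to 12 significant
    digits; a gene tied between a brain and a non-brain column is
    brain-and-elsewhere, never brain-unique.
    """
    if not catalog.brain_columns:
        raise ValueError("catalog defines no brain columns")
    if result.smoothed.gene_ids != seed_signal.gene_ids:
        raise ValueError("diffusion result and seed signal gene orders are misaligned")
    values = round_significant(result.smoothed.values)
    brain = catalog.brain_mask()
    if brain.all():
        raise ValueError("catalog has no non-brain columns to compare against")
    row_max = values.max(axis=1)
    brain_max = values[:, brain].max(axis=1)
    other_max = values[:, ~brain].max(axis=1)
    is_seed = np.asarray(seed_signal.values) > 0

    classes = np.where(
        row_max <= 0,
        CLASS_NO_SIGNAL,
        np.where(
            brain_max > other_max,
            CLASS_BRAIN_UNIQUE,
            np.where(brain_max == row_max, CLASS_BRAIN_AND_ELSEWHERE, CLASS_NON_BRAIN),
        ),
    )
    labels = catalog.labels()
    argmax_cols = [
        ";".join(labels[j] for j in np.flatnonzero(values[i] == row_max[i])) if row_max[i] > 0 else ""
        for i in range(values.shape[0])
    ]
    # dense rank per column, 1 = highest intensity
    order = np.argsort(-values, axis=0, kind="stable")
    column_ranks = np.empty_like(values, dtype=np.int64)
    rows = np.arange(values.shape[0])
    for j in range(values.shape[1]):
        column_ranks[order[:, j], j] = rows + 1
    table = pd.DataFrame(
        {
            "gene_id": result.smoothed.gene_ids,
            "class": classes,
            "is_seed": is_seed,
            "max_intensity": row_max,
            "argmax_columns": argmax_cols,
        }
    )
    return RankedGeneTable(table=table, intensities=values,
                           column_ranks=column_ranks, catalog=catalog)


def summarize_by_column(ranked: RankedGeneTable) -> pd.DataFrame:
    """Per (tissue, cell) column: how many genes peak there, seed vs novel.

    A gene tied across several columns is counted once per tied column, so
    the counts sum to at least the number of genes with positive signal.
    """
    labels = ranked.catalog.labels()
    label_to_j = {lab: j for j, lab in enumerate(labels)}
    seed_counts = np.zeros(len(labels), dtype=np.int64)
    novel_counts = np.zeros(len(labels), dtype=np.int64)
    for cols, is_seed in zip(ranked.table["argmax_columns"], ranked.table["is_seed"]):
        if not cols:
            continue
        for lab in cols.split(";"):
            j = label_to_j[lab]
            if is_seed:
                seed_counts[j] += 1
            else:
                novel_counts[j] += 1
    tissues, cells = zip(*ranked.catalog.columns)
    return pd.DataFrame(
        {
            "tissue": tissues,
            "cell_type": cells,
            "n_seed_top": seed_counts,
            "n_novel_top": novel_counts,
            "n_top": seed_counts + novel_counts,
        }
    )


def gene_max_in_brain(values_row: np.ndarray, brain_mask: np.ndarray) -> bool:
    """Whether a diffused profile attains its (positive) maximum in a brain column."""
    v = round_significant(values_row)
    m = v.max()
    return bool(m > 0 and v[brain_mask].max() == m)
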
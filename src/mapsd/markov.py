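"""Row-stochastic Markov operator built from the affinity matrix.

The transition matrix is the random-walk normalization M = D^-1 A, where
D is the diagonal degree matrix with D_ii = sum_j a_ij.  Entry m_ij is the
one-step probability of a random walk moving from protein i to protein j.
Powers of M are always applied as repeated sparse products, never formed
densely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .network import AffinityMatrix

logger = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-12


class DegenerateGraphError(ValueError):
    """Raised when zero-degree nodes make D^-1 undefined."""


@dataclass
class TransitionMatrix:
    """Row-stochastic operator M = D^-1 A with its source degrees."""

    values: sp.csr_matrix
    source_degrees: np.ndarray
    nodes: list[str]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def operator(self, orientation: str = "left") -> sp.csr_matrix:
        """M itself, or its transpose for the mass-spreading variant."""
        if orientation == "left":
            return self.values
        if orientation == "transpose":
            return self.values.T.tocsr()
        raise ValueError(f"unknown operator orientation {orientation!r}")


def degree_vector(A: AffinityMatrix) -> np.ndarray:
    """Diagonal of the degree matrix: D_ii = sum_j a_ij."""
    return np.asarray(A.values.sum(axis=1)).ravel()


def transition_matrix(A: AffinityMatrix) -> TransitionMatrix:
    """Row-normalize the affinity matrix into M = D^-1 A.

    Raises :class:`DegenerateGraphError` naming the offending nodes if any
    node has zero degree; isolates must be removed (and their signal carried
    through unchanged) before the operator is built.
    """
    deg = degree_vector(A)
    zero = np.flatnonzero(deg == 0)
    if zero.size:
        names = [A.nodes[i] for i in zero[:10]]
        raise DegenerateGraphError(
            f"{zero.size} zero-degree node(s) (e.g. {names}); remove isolates first"
        )
    inv_d = sp.diags(1.0 / deg)
    M = (inv_d @ A.values).tocsr()
    row_sums = np.asarray(M.sum(axis=1)).ravel()
    if not np.allclose(row_sums, 1.0, atol=ROW_SUM_TOL, rtol=0.0):
        worst = float(np.max(np.abs(row_sums - 1.0)))
        raise DegenerateGraphError(f"row normalization failed (max deviation {worst:g})")
    return TransitionMatrix(values=M, source_degrees=deg, nodes=list(A.nodes))


def apply_power(M: TransitionMatrix, X: np.ndarray, t: int, orientation: str = "left") -> np.ndarray:
    """Compute M^t X by t successive sparse multiplications."""
    if t < 0:
        raise ValueError("t must be non-negative")
    X = np.asarray(X, dtype=float)
    squeeze = X.ndim == 1
    if squeeze:
        X = X[:, None]
    if X.shape[0] != M.n:
        raise ValueError(f"X has {X.shape[0]} rows, expected {M.n}")
    op = M.operator(orientation)
    out = X
    for _ in range(t):
        out = op @ out
    return out.ravel() if squeeze else out
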
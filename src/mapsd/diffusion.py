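"""Iterative Markov smoothing with the smoothness-rate stopping criterion.

Diffusion computes S^t = M^t S* by repeated application of the transition
operator.  Unbounded smoothing converges to a constant profile per connected
component and destroys discriminative information, so iteration stops at the
first step t where the smoothness rate

    R(t) = SSE / SST,
    SSE = sum_ij (M^{t+1}S* - M^t S*)_ij^2,
    SST = sum_ij (M^{t+1}S* + M^t S*)_ij^2,

drops to the threshold (default 0.05): once consecutive states barely
differ relative to their magnitude, a further step only over-smooths.
The accepted state is S^t, not S^{t+1}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .markov import TransitionMatrix, apply_power
from .signals import TissueSignalMatrix

logger = logging.getLogger(__name__)

DEFAULT_R_THRESHOLD = 0.05
DEFAULT_T_MAX = 50


class DiffusionError(RuntimeError):
    """Raised on numerical failure during diffusion."""


@dataclass
class SmoothnessDiagnostics:
    """Per-step (t, SSE, SST, R) records."""

    steps: list[tuple[int, float, float, float]] = field(default_factory=list)

    def record(self, t: int, sse: float, sst: float, r: float) -> None:
        self.steps.append((t, sse, sst, r))

    @property
    def r_values(self) -> list[float]:
        return [s[3] for s in self.steps]


@dataclass
class DiffusionResult:
    smoothed: TissueSignalMatrix
    t_stop: int
    diagnostics: SmoothnessDiagnostics
    capped: bool
    config: dict


def _rate(prev: np.ndarray, nxt: np.ndarray) -> tuple[float, float, float]:
    err = nxt - prev
    tot = nxt + prev
    sse = float(np.sum(err * err))
    sst = float(np.sum(tot * tot))
    if sst == 0.0:
        logger.warning("all-zero signal state: R defined as 0 (degenerate input)")
        return sse, sst, 0.0
    return sse, sst, sse / sst


def smoothness_rate(
    M: TransitionMatrix, X: np.ndarray, t: int, orientation: str = "left"
) -> tuple[float, float, float]:
    """(SSE, SST, R) comparing M^{t+1}X against M^t X.

    R = 0 is returned (with a warning) when both states are identically
    zero, since an all-zero signal is already maximally smooth.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    cur = apply_power(M, X, t, orientation)
    nxt = apply_power(M, cur, 1, orientation)
    return _rate(cur, nxt)


def run_diffusion(
    M: TransitionMatrix,
    S_star: TissueSignalMatrix,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    t_max: int = DEFAULT_T_MAX,
    orientation: str = "left",
    per_column: bool = False,
) -> DiffusionResult:
    """Diffuse S* under M until R(t) <= ``r_threshold`` (or ``t_max``).

    States are advanced incrementally (one sparse product per step, never
    re-multiplying from scratch).  The returned matrix is S^t at the first
    accepted t; if the cap is reached first, S^{t_max} with ``capped`` set.
    By default R sums jointly over all genes and columns; ``per_column``
    instead requires every column's own rate to reach the threshold, and
    the recorded R is the worst (largest) column rate.
    """
    if not (0.0 < r_threshold < 1.0):
        raise ValueError("r_threshold must lie in (0, 1)")
    if t_max < 1:
        raise ValueError("t_max must be at least 1")
    X = np.asarray(S_star.values, dtype=float)
    if X.shape[0] != M.n:
        raise ValueError(f"signal matrix has {X.shape[0]} rows, operator expects {M.n}")
    op = M.operator(orientation)
    diagnostics = SmoothnessDiagnostics()
    cur = op @ X  # S^1
    t = 1
    capped = False
    while True:
        nxt = op @ cur  # S^{t+1}
        if not np.isfinite(nxt).all():
            raise DiffusionError(f"non-finite values at diffusion step {t + 1}")
        if per_column:
            err2 = np.sum((nxt - cur) ** 2, axis=0)
            tot2 = np.sum((nxt + cur) ** 2, axis=0)
            rates = np.divide(err2, tot2, out=np.zeros_like(err2), where=tot2 > 0)
            sse, sst, r = float(err2.sum()), float(tot2.sum()), float(rates.max(initial=0.0))
        else:
            sse, sst, r = _rate(cur, nxt)
        diagnostics.record(t, sse, sst, r)
        if r <= r_threshold:
            break
        if t >= t_max:
            capped = True
            logger.warning("diffusion capped at t_max=%d with R=%g", t_max, r)
            break
        cur = nxt
        t += 1
    smoothed = TissueSignalMatrix(values=cur, gene_ids=list(S_star.gene_ids),
                                  catalog=S_star.catalog)
    return DiffusionResult(
        smoothed=smoothed,
        t_stop=t,
        diagnostics=diagnostics,
        capped=capped,
        config={"r_threshold": r_threshold, "t_max": t_max, "orientation": orientation},
    )
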
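"""Time-delay embedding, recurrence distance matrices, and their change points.

A recurrence plot is the time x time matrix of Euclidean distances between
time-delay embedded state vectors; recurrent regimes appear as low-distance
blocks, transitions as block boundaries.  As a first-order quantification of
such boundaries, change-point analysis is applied to every row of the
(unthresholded) distance matrix and the detected column indices are pooled:
the arithmetic mean of the row-wise mean-change indices, and of the row-wise
variance-change indices, each rounded to the nearest integer, localize the
regime shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .changepoint import ChangePoint, CpaConfig, detect_mean_and_variance
from .series import TimeSeries


@dataclass(frozen=True)
class EmbeddingConfig:
    dimension: int = 3
    delay: int = 1

    def __post_init__(self) -> None:
        if self.dimension < 1 or self.delay < 1:
            raise ValueError("embedding dimension and delay must be >= 1")


@dataclass(frozen=True)
class RecurrenceMatrix:
    """Pairwise embedded-state distances; symmetric with zero diagonal.

    ``t_start`` is the original time index of the first embedded vector
    (its first coordinate), used to map matrix columns back to series time.
    """

    distances: np.ndarray
    config: EmbeddingConfig
    t_start: int = 1

    def __post_init__(self) -> None:
        d = self.distances
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] < 2:
            raise ValueError("distance matrix must be square with M >= 2")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")


def embed(s: TimeSeries, cfg: EmbeddingConfig = EmbeddingConfig()) -> np.ndarray:
    """Time-delay embedding: vector ``i`` = ``(x_i, x_{i+tau}, ..., x_{i+(d-1)tau})``.

    Returns an ``M x d`` array with ``M = N - (d - 1) * tau``.
    """
    d, tau = cfg.dimension, cfg.delay
    n = len(s)
    m = n - (d - 1) * tau
    if m < 1:
        raise ValueError(f"series of length {n} too short to embed (d={d}, tau={tau})")
    cols = [s.values[j * tau: j * tau + m] for j in range(d)]
    return np.column_stack(cols)


def distance_matrix(
    vectors: np.ndarray,
    config: EmbeddingConfig = EmbeddingConfig(),
    t_start: int = 1,
) -> RecurrenceMatrix:
    """Euclidean distance matrix between embedded state vectors."""
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    if v.shape[0] < 2:
        raise ValueError("need at least 2 vectors")
    return RecurrenceMatrix(squareform(pdist(v)), config=config, t_start=t_start)


def recurrence_matrix(
    s: TimeSeries, cfg: EmbeddingConfig = EmbeddingConfig()
) -> RecurrenceMatrix:
    """Embed a series and build its recurrence distance matrix."""
    return distance_matrix(embed(s, cfg), config=cfg, t_start=s.t0)


def rp_changepoints(
    m: RecurrenceMatrix, cpa: CpaConfig = CpaConfig()
) -> list[ChangePoint]:
    """Row-wise CPA of a recurrence matrix, pooled per statistic.

    Each row is scanned for one mean change and one variance change; detected
    column indices are pooled separately per statistic and the arithmetic
    mean (over rows that detected anything), rounded to the nearest integer,
    is reported.  Rows without a detection are skipped, not counted as zero.
    Indices are mapped to original time via the first embedding coordinate.
    """
    n_rows = m.distances.shape[0]
    if n_rows < 2 * cpa.min_segment:
        return []
    found: dict[str, list[int]] = {"mean": [], "variance": []}
    drops: dict[str, list[float]] = {"mean": [], "variance": []}
    for row in m.distances:
        for cp in detect_mean_and_variance(row, penalty=cpa.penalty,
                                           min_segment=cpa.min_segment):
            found[cp.statistic].append(cp.index)
            drops[cp.statistic].append(cp.cost_drop)
    out = []
    for statistic in ("mean", "variance"):
        if found[statistic]:
            pooled = int(np.rint(np.mean(found[statistic])))
            out.append(ChangePoint(index=pooled + m.t_start - 1,
                                   statistic=statistic,  # type: ignore[arg-type]
                                   cost_drop=float(np.mean(drops[statistic]))))
    return out
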
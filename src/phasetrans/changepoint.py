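"""Penalized single-split change-point analysis (CPA).

A series ``x`` of length N contains a change point if it can be split into
two segments ``x1 = x[1..b-1]`` and ``x2 = x[b..N]`` such that

    C(x1) + C(x2) + k < C(x)

where ``C`` is a cost functional and ``k`` a penalty.  For mean changes the
cost is ``C(x) = N * var(x)`` (sample variance, denominator N-1); for
variance changes it is the Gaussian log-likelihood cost
``C(x) = N * ln(max(var(x), eps))``.  The split index ``b`` minimizing
``C(x1) + C(x2)`` over all admissible positions is returned when the
improvement beats the penalty; ties are broken toward the smallest ``b``.
Indices are 1-based and denote the first point of the *new* segment.

At most one mean change and one variance change are detected per series;
the second-order convergence layer pools such detections across many
indicator series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np

VAR_FLOOR = 1e-12

Statistic = Literal["mean", "variance"]


@dataclass(frozen=True)
class CpaConfig:
    """Detection settings: penalty ``k``, minimum segment length, statistic."""

    penalty: float = 1.0
    min_segment: int = 2
    statistic: Statistic = "mean"

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("penalty must be nonnegative")
        if self.min_segment < 1:
            raise ValueError("min_segment must be >= 1")
        if self.statistic == "variance" and self.min_segment < 2:
            raise ValueError("variance detection needs min_segment >= 2")
        if self.statistic not in ("mean", "variance"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclass(frozen=True)
class ChangePoint:
    """A detected change: 1-based first index of the new segment."""

    index: int
    statistic: Statistic
    cost_drop: float


def cost_mean(x: Sequence[float]) -> float:
    """Cost of a segment under the constant-mean model: ``N * var(x)``.

    Returns 0 for a single point (a singleton fits its mean perfectly).
    """
    arr = np.asarray(x, dtype=float)
    if arr.size < 1:
        raise ValueError("cost undefined for empty segment")
    if arr.size < 2:
        return 0.0
    return float(arr.size * np.var(arr, ddof=1))


def cost_variance(x: Sequence[float]) -> float:
    """Cost under the constant-variance model: ``N * ln(max(var(x), eps))``."""
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValueError("variance cost needs at least 2 points")
    v = max(float(np.var(arr, ddof=1)), VAR_FLOOR)
    return float(arr.size * np.log(v))


def _segment_costs(x: np.ndarray, statistic: Statistic):
    """Vectorized split-scan costs via prefix sums.

    Returns (split_sizes n1, left costs, right costs, total cost) for every
    admissible left-segment size ``n1``.
    """
    n = x.size
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def seg_ss(i: np.ndarray, j: np.ndarray) -> np.ndarray:
        # sum of squared deviations of x[i..j-1] (0-based half-open)
        cnt = j - i
        s = cs[j] - cs[i]
        ss = cs2[j] - cs2[i] - s * s / cnt
        return np.maximum(ss, 0.0)

    n1 = np.arange(1, n)  # candidate left-segment sizes
    i0 = np.zeros_like(n1)
    ss1 = seg_ss(i0, n1)
    ss2 = seg_ss(n1, np.full_like(n1, n))
    n2 = n - n1
    if statistic == "mean":
        with np.errstate(divide="ignore", invalid="ignore"):
            c1 = np.where(n1 >= 2, n1 * ss1 / np.maximum(n1 - 1, 1), 0.0)
            c2 = np.where(n2 >= 2, n2 * ss2 / np.maximum(n2 - 1, 1), 0.0)
        total = cost_mean(x)
    else:
        v1 = np.maximum(ss1 / np.maximum(n1 - 1, 1), VAR_FLOOR)
        v2 = np.maximum(ss2 / np.maximum(n2 - 1, 1), VAR_FLOOR)
        c1 = n1 * np.log(v1)
        c2 = n2 * np.log(v2)
        total = cost_variance(x)
    return n1, c1, c2, total


def detect_single_change(
    x: Sequence[float], cfg: CpaConfig = CpaConfig()
) -> Optional[ChangePoint]:
    """Exhaustive single-split detection of one change point.

    Evaluates every admissible split ``b`` (both segments at least
    ``min_segment`` long) and returns the one minimizing the summed segment
    costs, provided the improvement over the unsplit cost strictly exceeds
    the penalty.  Returns ``None`` when the series is too short or no split
    beats the penalty.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size < 2 * cfg.min_segment:
        return None
    n1, c1, c2, total = _segment_costs(arr, cfg.statistic)
    admissible = (n1 >= cfg.min_segment) & ((arr.size - n1) >= cfg.min_segment)
    if not np.any(admissible):
        return None
    split_cost = np.where(admissible, c1 + c2, np.inf)
    best = int(np.argmin(split_cost))  # first occurrence -> smallest b
    drop = total - float(split_cost[best])
    if drop > cfg.penalty:
        return ChangePoint(index=int(n1[best]) + 1, statistic=cfg.statistic,
                           cost_drop=drop)
    return None


def detect_mean_and_variance(
    x: Sequence[float], penalty: float = 1.0, min_segment: int = 2
) -> list[ChangePoint]:
    """Run mean- and variance-change detection; at most one point each.

    The variance pass operates on segment variances directly (variance is
    invariant to centering each candidate segment on its own mean).
    """
    base = CpaConfig(penalty=penalty, min_segment=max(min_segment, 2))
    out = []
    for statistic in ("mean", "variance"):
        cp = detect_single_change(x, replace(base, statistic=statistic))
        if cp is not None:
            out.append(cp)
    return out
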